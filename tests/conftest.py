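import numpy as np
import pandas as pd
import pytest

import phosnet as pn
from phosnet.config import AnalysisConfig, PlantedEdge, SyntheticConfig


@pytest.fixture(scope="session")
def fixture_study():
    """The packaged deterministic 8x10 dataset."""
    return pn.tiny_fixture()


@pytest.fixture(scope="session")
def fixture_network(fixture_study):
    matrix, _, _, _ = fixture_study
    filtered = pn.filter_low_frequency(matrix)
    return pn.CooccurrenceModel(filtered).fit(seed=0)


def recovery_config() -> SyntheticConfig:
    """Benchmark conditions for planted-edge recovery: 24 bands, 10 disjoint
    planted edges of strength 0.8 covering both signs and all three kingdom
    classes, low idiosyncratic noise, no dropout and no treatment shift (the
    benchmark isolates the inference stage from those confounders)."""
    edges = [
        PlantedEdge(f"b{2 * k + 1:03d}", f"b{2 * k + 2:03d}", 1 if k % 2 else -1, 0.8)
        for k in range(6)
    ]
    edges += [
        PlantedEdge(f"f{2 * k + 1:03d}", f"f{2 * k + 2:03d}", 1 if k % 2 else -1, 0.8)
        for k in range(3)
    ]
    edges.append(PlantedEdge("b013", "f007", 1, 0.8))
    return SyntheticConfig(
        n_bacteria_bands=14,
        n_fungi_bands=10,
        planted_edges=tuple(edges),
        zero_inflation=0.0,
        noise_sd=0.15,
        source_effect_sd=0.0,
        latent_scale=0.5,
    )


@pytest.fixture(scope="session")
def default_study():
    """One full-size synthetic study (32 samples x 157 bands)."""
    return pn.generate_study(seed=11)


def toy_network(edges, kingdoms, isolated=()):
    """Build a MicrobialNetwork from (u, v, sign) triples for tests."""
    import networkx as nx

    g = nx.Graph(group="toy")
    for node, kd in kingdoms.items():
        g.add_node(node, kingdom=kd)
    for node in isolated:
        if node not in g:
            g.add_node(node, kingdom="bacteria")
    for u, v, sign in edges:
        g.add_edge(u, v, sign=sign, rho_spearman=float(sign), rho_pearson=float(sign),
                   p_spearman=0.01, p_pearson=0.01)
    return pn.MicrobialNetwork(g, group="toy")
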