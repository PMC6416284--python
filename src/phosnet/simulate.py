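"""Synthetic study generator.

Emulates the greenhouse design this pipeline targets: 32 pots (4 phosphate
sources x 2 inoculum levels x 4 replicates), a DGGE fingerprint of 157 bands
(90 bacterial, 67 fungal), mycorrhizal colonization declining with %P2O5, and
total dry matter peaking at an interior phosphate solubility.

The band matrix is built from a latent Gaussian factor model: every planted
edge contributes one shared standard-normal factor per sample; the two bands
of the edge load +/- sqrt(strength) on it, so the noise-free latent
correlation of the pair equals the planted strength with the planted sign.
Idiosyncratic Gaussian noise (``noise_sd``) attenuates that correlation, the
latent score is exponentiated to a positive lognormal intensity, and a
Bernoulli presence mask (``zero_inflation``) zeroes a fraction of entries —
zeros create the tied ranks typical of gel profiles.  Per-(band, source)
log-intensity offsets plant a community-composition effect of phosphate
source; the analogous inoculum offsets default to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PlantedEdge, SyntheticConfig
from .data import BandMatrix, PhenotypeTable, SampleTable

__all__ = ["PlantedTruth", "generate_study", "generate_phenotypes", "tiny_fixture", "dm_curve_value"]


@dataclass
class PlantedTruth:
    """Ground truth of one synthetic study, for recovery tests."""

    edges: tuple[PlantedEdge, ...]
    factors: pd.DataFrame  # samples x planted edges, the shared latent factors
    dm_curve: tuple[str, float, float, float]
    colonization_curve: tuple[float, float]

    def edge_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted((e.band_i, e.band_j))) for e in self.edges}

    def signed_edge_set(self) -> set[tuple[str, str, int]]:
        return {(*sorted((e.band_i, e.band_j)), e.sign) for e in self.edges}


def _design_table(config: SyntheticConfig) -> SampleTable:
    rows = []
    i = 0
    for source, p2o5 in config.sources.items():
        for inoc in (True, False):
            for rep in range(1, config.n_replicates + 1):
                i += 1
                rows.append(
                    {
                        "sample_id": f"S{i:02d}",
                        "source": source,
                        "p2o5_percent": p2o5,
                        "inoculum": inoc,
                        "replicate": rep,
                    }
                )
    df = pd.DataFrame(rows).set_index("sample_id")
    return SampleTable(df)


def dm_curve_value(curve: tuple[str, float, float, float], x: np.ndarray | float) -> np.ndarray | float:
    """Evaluate a dry-matter dose-response curve at %P2O5 ``x``."""
    form, a, b, c = curve
    x = np.asarray(x, dtype=float)
    if form == "exp":
        return a * np.exp(b * x)
    if form == "exp_offset":
        return a * np.exp(b * x) + c
    if form == "peaked":
        return a * x * np.exp(b * x)
    if form == "peaked_offset":
        return a * x * np.exp(b * x) + c
    raise ValueError(f"unknown curve form {form!r}")


def generate_study(
    config: SyntheticConfig | None = None, seed: int = 0
) -> tuple[BandMatrix, SampleTable, PhenotypeTable, PlantedTruth]:
    """Generate one full synthetic study.

    Returns the band matrix, sample metadata, phenotypes and the generative
    ground truth.  Identical ``(config, seed)`` give bit-identical outputs.
    """
    if config is None:
        config = SyntheticConfig()
    band_ids = config.band_ids()
    band_index = {b: i for i, b in enumerate(band_ids)}
    for e in config.planted_edges:
        for b in (e.band_i, e.band_j):
            if b not in band_index:
                raise ValueError(f"planted edge references unknown band {b!r}")

    samples = _design_table(config)
    n, m = config.n_samples, config.n_bands
    rng = np.random.default_rng(seed)

    edges = tuple(config.planted_edges)
    n_edges = len(edges)
    factors = rng.standard_normal((n, n_edges))
    loadings = np.zeros((m, n_edges))
    for k, e in enumerate(edges):
        loadings[band_index[e.band_i], k] = np.sqrt(e.strength)
        loadings[band_index[e.band_j], k] = e.sign * np.sqrt(e.strength)

    z = factors @ loadings.T + config.noise_sd * rng.standard_normal((n, m))

    base = rng.normal(2.0, 0.5, size=m)  # per-band mean log-intensity
    src_codes = pd.Categorical(samples.table["source"]).codes
    src_shift = rng.normal(0.0, config.source_effect_sd, size=(len(config.sources), m))
    inoc_shift = rng.normal(0.0, config.inoculum_effect_sd, size=(2, m))
    inoc_codes = samples.table["inoculum"].astype(int).to_numpy()

    log_intensity = (
        base[None, :] + src_shift[src_codes] + inoc_shift[inoc_codes]
        + config.latent_scale * z
    )
    intensity = np.exp(log_intensity)
    mask = rng.random((n, m)) >= config.zero_inflation
    intensity = intensity * mask

    matrix = BandMatrix(
        pd.DataFrame(intensity, index=samples.sample_ids, columns=band_ids),
        {b: ("bacteria" if b.startswith("b") else "fungi") for b in band_ids},
    )
    # child seed below 2**31 so callers can re-derive it portably
    pheno = generate_phenotypes(samples, config, seed=(seed * 7919 + 1) % (2**31))
    truth = PlantedTruth(
        edges=edges,
        factors=pd.DataFrame(factors, index=samples.sample_ids,
                             columns=[f"{e.band_i}--{e.band_j}" for e in edges]),
        dm_curve=config.dm_curve,
        colonization_curve=config.colonization_curve,
    )
    return matrix, samples, pheno, truth


def generate_phenotypes(
    samples: SampleTable, config: SyntheticConfig | None = None, seed: int = 0
) -> PhenotypeTable:
    """Dry matter and colonization for every sample in ``samples``.

    Colonization is ``max(0, intercept + slope * %P2O5 + noise)`` for
    inoculated pots and exactly 0 otherwise; dry matter follows the configured
    dose-response curve plus Gaussian noise (floored at a small positive
    value, since an oven-dried plant always weighs something).
    """
    if config is None:
        config = SyntheticConfig()
    rng = np.random.default_rng(seed)
    df = samples.table
    x = df["p2o5_percent"].to_numpy(dtype=float)
    inoc = df["inoculum"].astype(bool).to_numpy()

    dm = dm_curve_value(config.dm_curve, x) + config.dm_noise_sd * rng.standard_normal(len(df))
    dm = np.maximum(dm, 0.1)

    c0, c1 = config.colonization_curve
    col = c0 + c1 * x + config.colonization_noise_sd * rng.standard_normal(len(df))
    col = np.clip(col, 0.0, 100.0)
    col[~inoc] = 0.0

    pheno = pd.DataFrame(
        {"total_dry_matter": dm, "colonization_index": col}, index=df.index
    )
    return PhenotypeTable(pheno, samples)


# ---------------------------------------------------------------------------
# tiny deterministic fixture
# ---------------------------------------------------------------------------

_FIXTURE_BANDS: dict[str, list[float]] = {
    # bacteria
    "b1": [1, 2, 3, 4, 5, 6, 7, 8],
    "b2": [2, 4, 6, 8, 10, 12, 14, 16],    # = 2 * b1
    "b3": [5, 1, 4, 2, 8, 3, 7, 6],        # unrelated scramble
    "b4": [3, 6, 2, 7, 1, 8, 5, 4],        # unrelated scramble
    "b5": [5, 8, 1, 4, 7, 2, 6, 3],
    "b6": [4, 1, 8, 5, 2, 7, 3, 6],        # = 9 - b5
    # fungi
    "b7": [6, 9, 2, 5, 8, 3, 7, 4],        # = b5 + 1
    "b8": [5, 5, 5, 5, 5, 5, 5, 5],        # constant: correlations undefined
    "b9": [0, 0, 0, 4, 0, 0, 0, 0],        # present in 1/8 samples: filtered
    "b10": [4, 6, 7, 2, 1, 3, 8, 5],       # unrelated scramble
}

_FIXTURE_EDGES = (
    PlantedEdge("b1", "b2", 1, 1.0),
    PlantedEdge("b5", "b6", -1, 1.0),
    PlantedEdge("b5", "b7", 1, 1.0),
    PlantedEdge("b6", "b7", -1, 1.0),
)


def tiny_fixture() -> tuple[BandMatrix, SampleTable, PhenotypeTable, PlantedTruth]:
    """Hand-written 8-sample x 10-band dataset with verifiable correlations.

    Six bacterial and four fungal bands; b2 is an exact rescaling of b1, the
    trio b5/b6/b7 is mutually perfectly rank-correlated (b6 reversed), b8 is
    constant, b9 occurs in a single sample (removed by the 25% filter), and
    b3/b4/b10 are unrelated scrambles.
    """
    config = SyntheticConfig()
    rows = []
    for i, (source, p2o5) in enumerate(config.sources.items()):
        for j, inoc in enumerate((True, False)):
            rows.append(
                {
                    "sample_id": f"s{2 * i + j + 1}",
                    "source": source,
                    "p2o5_percent": p2o5,
                    "inoculum": inoc,
                    "replicate": 1,
                }
            )
    samples = SampleTable(pd.DataFrame(rows).set_index("sample_id"))

    matrix = BandMatrix(
        pd.DataFrame(_FIXTURE_BANDS, index=samples.sample_ids, dtype=float),
        {b: ("bacteria" if int(b[1:]) <= 6 else "fungi") for b in _FIXTURE_BANDS},
    )

    x = samples.table["p2o5_percent"].to_numpy(dtype=float)
    inoc = samples.table["inoculum"].astype(bool).to_numpy()
    dm = np.asarray(dm_curve_value(config.dm_curve, x), dtype=float)
    c0, c1 = config.colonization_curve
    col = np.where(inoc, np.maximum(c0 + c1 * x, 0.0), 0.0)
    pheno = PhenotypeTable(
        pd.DataFrame(
            {"total_dry_matter": dm, "colonization_index": col},
            index=samples.sample_ids,
        ),
        samples,
    )
    truth = PlantedTruth(
        edges=_FIXTURE_EDGES,
        factors=pd.DataFrame(index=samples.sample_ids),
        dm_curve=config.dm_curve,
        colonization_curve=config.colonization_curve,
    )
    return matrix, samples, pheno, truth
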