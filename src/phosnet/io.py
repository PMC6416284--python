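"""Result writers: GraphML + TSV edge lists, topology tables, fit tables,
surface grids and optimum JSON.  All writes are deterministic for identical
inputs (fixed column order, fixed float formatting)."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .community import Dendrogram, DistanceMatrix, Ordination, PermanovaResults
from .network import MicrobialNetwork, NetworkResults, TopologyReport
from .surface import ExponentialFit, OptimumEstimate, SurfaceGrid

__all__ = ["export_results", "write_network", "write_topology", "read_network"]

_EDGE_COLUMNS = ["band_i", "band_j", "sign", "rho_spearman", "rho_pearson", "p_spearman", "p_pearson"]


def write_network(network: MicrobialNetwork, out_dir: str | Path, stem: str | None = None) -> None:
    """Write one network as GraphML plus a TSV edge list."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = stem or f"network_{network.group}"
    nx.write_graphml(network.graph, out / f"{stem}.graphml")
    rows = [
        {
            "band_i": u,
            "band_j": v,
            "sign": attrs["sign"],
            "rho_spearman": attrs["rho_spearman"],
            "rho_pearson": attrs["rho_pearson"],
            "p_spearman": attrs["p_spearman"],
            "p_pearson": attrs["p_pearson"],
        }
        for u, v, attrs in sorted(network.graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=_EDGE_COLUMNS).to_csv(
        out / f"{stem}_edges.tsv", sep="\t", index=False, float_format="%.6g"
    )


def read_network(graphml_path: str | Path, group: str = "all") -> MicrobialNetwork:
    g = nx.read_graphml(graphml_path)
    return MicrobialNetwork(nx.Graph(g), group=g.graph.get("group", group))


def write_topology(reports: list[TopologyReport], path: str | Path) -> None:
    """One TSV row per group network."""
    rows = [r.to_row() for r in reports]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def export_results(objects, out_dir: str | Path) -> list[Path]:
    """Write any mix of pipeline outputs into ``out_dir``.

    Dispatches on type; returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    reports: list[TopologyReport] = []
    fits: list[ExponentialFit] = []
    for obj in objects:
        if isinstance(obj, NetworkResults):
            write_network(obj.network, out)
            written.append(out / f"network_{obj.network.group}.graphml")
            reports.append(obj.report)
        elif isinstance(obj, MicrobialNetwork):
            write_network(obj, out)
            written.append(out / f"network_{obj.group}.graphml")
        elif isinstance(obj, TopologyReport):
            reports.append(obj)
        elif isinstance(obj, PermanovaResults):
            path = out / "permanova.tsv"
            obj.table.to_csv(path, sep="\t", float_format="%.6g")
            written.append(path)
        elif isinstance(obj, Ordination):
            path = out / "ordination.tsv"
            obj.coordinates.to_csv(path, sep="\t", float_format="%.6g", index_label="sample_id")
            written.append(path)
        elif isinstance(obj, DistanceMatrix):
            path = out / "distances.tsv"
            obj.to_frame().to_csv(path, sep="\t", float_format="%.6g", index_label="sample_id")
            written.append(path)
        elif isinstance(obj, Dendrogram):
            path = out / "dendrogram.nwk"
            path.write_text(obj.to_newick() + "\n")
            written.append(path)
        elif isinstance(obj, ExponentialFit):
            fits.append(obj)
        elif isinstance(obj, SurfaceGrid):
            path = out / "surface.tsv"
            # full precision so a scan of the exported grid reproduces argmax
            obj.grid.to_csv(path, sep="\t", index=False, float_format="%.12g")
            written.append(path)
        elif isinstance(obj, OptimumEstimate):
            path = out / "optimum.json"
            path.write_text(json.dumps(obj.__dict__, indent=2, sort_keys=True) + "\n")
            written.append(path)
        else:
            raise TypeError(f"cannot export object of type {type(obj).__name__}")
    if reports:
        path = out / "topology.tsv"
        write_topology(reports, path)
        written.append(path)
    if fits:
        path = out / "fits.tsv"
        rows = [
            {
                "form": f.form,
                "params": ",".join(f"{v:.8g}" for v in f.params),
                "r_squared": f.r_squared,
                "rse": f.rse,
                "p_value": f.p_value,
                "n": f.n,
            }
            for f in fits
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)
    return written
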