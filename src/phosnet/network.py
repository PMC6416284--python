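"""Dual-correlation signed co-occurrence network inference and topology.

An edge between two gel bands requires *both* the Spearman and the Pearson
correlation across samples to be significant (two-sided p < alpha for each)
with agreeing sign; the shared sign becomes the edge sign.  Every band that
survived the frequency filter stays in the graph as a node whether or not it
gains an edge, which is what separates the *total* node panel from the
*interacting* (degree >= 1) nodes in the topology report.

p-values use the t transform with n-2 degrees of freedom (Spearman on
midranks, tie-corrected); for very small sample subsets the t approximation
is poor and an exact permutation null over all orderings of one band replaces
both (auto-activated at n <= 10, full enumeration up to 8 samples and a
deterministic subsample beyond).

Community structure uses the spinglass algorithm (statistical-physics energy
minimisation over node spin states), run per connected component because the
energy function is only defined on connected graphs; modularity of the final
partition is Newman-Girvan.
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
from networkx.algorithms.community import modularity as nx_modularity
from scipy import stats

from .config import AnalysisConfig
from .data import BandMatrix, SampleTable, ValidationError

__all__ = [
    "CorrelationPair",
    "MicrobialNetwork",
    "EdgeClassCounts",
    "TopologyReport",
    "CooccurrenceModel",
    "NetworkResults",
    "correlate_pairs",
    "build_network",
    "classify_edges",
    "detect_communities",
    "topology_report",
    "infer_networks_by_group",
]


@dataclass(frozen=True)
class CorrelationPair:
    band_i: str
    band_j: str
    rho_spearman: float
    p_spearman: float
    rho_pearson: float
    p_pearson: float
    n_samples: int
    valid: bool = True


@dataclass
class MicrobialNetwork:
    """Signed, kingdom-labelled co-occurrence graph.

    Nodes carry a ``kingdom`` attribute; edges carry ``sign`` (+1/-1) and the
    four provenance statistics of the dual-correlation call.
    """

    graph: nx.Graph
    group: str = "all"

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def interacting_nodes(self) -> list[str]:
        return [n for n, d in self.graph.degree() if d > 0]


@dataclass(frozen=True)
class EdgeClassCounts:
    bb: int
    ff: int
    bf: int
    positives: int
    negatives: int

    @property
    def total(self) -> int:
        return self.bb + self.ff + self.bf


@dataclass
class TopologyReport:
    """Machine-readable topology summary of one group network.

    Average degree and graph density are each reported under both field
    conventions (2E/N vs E/N per interacting node; directed-pair density over
    the full panel vs undirected density over interacting nodes), because
    published tables mix them.
    """

    group: str
    total_nodes: int
    interacting_nodes: int
    pct_bacteria_nodes: float
    pct_fungi_nodes: float
    total_edges: int
    positives: int
    negatives: int
    pos_neg_ratio: float
    bb: int
    ff: int
    bf: int
    avg_degree_2e_n: float
    avg_degree_e_n: float
    density_total_directed: float
    density_interacting_directed: float
    n_communities: int
    modularity: float | None
    avg_clustering: float
    avg_path_length: float
    diameter: int

    def to_row(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# pairwise correlations
# ---------------------------------------------------------------------------

def _t_sf_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.isnan(t)] = 0.0  # |r| == 1 exactly
    return np.minimum(p, 1.0)


def _normalize_columns(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-center and scale to unit norm; flag constant columns."""
    centered = x - x.mean(axis=0)
    norms = np.linalg.norm(centered, axis=0)
    constant = norms < 1e-12
    safe = np.where(constant, 1.0, norms)
    return centered / safe, constant


def _permutation_matrix(n: int, max_perms: int, seed: int) -> np.ndarray:
    if math.factorial(n) <= max_perms:
        return np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    rng = np.random.default_rng(seed)
    perms = np.tile(np.arange(n), (max_perms, 1))
    for row in perms[1:]:  # keep identity in row 0
        rng.shuffle(row)
    return perms


def correlate_pairs(
    matrix: BandMatrix,
    binarize: bool = False,
    exact_max_n: int = 10,
    max_perms: int = 50_000,
    seed: int = 0,
) -> list[CorrelationPair]:
    """Spearman and Pearson statistics for every unordered band pair.

    Pearson r comes with a two-sided p from the t transform (n-2 df);
    Spearman rho is Pearson on midranks (ties averaged) with the analogous t
    approximation.  When ``n <= exact_max_n`` both approximations are
    replaced by a permutation p over orderings of one band (all n! orderings
    when feasible, otherwise ``max_perms`` seeded shuffles including the
    identity).  Constant bands yield invalid pairs, excluded from edge
    calling.
    """
    n = matrix.n_samples
    if n < 4:
        raise ValidationError("need at least 4 samples for edge calling")
    values = matrix.values()
    if binarize:
        values = (values > 0).astype(float)
    ranks = np.apply_along_axis(stats.rankdata, 0, values)

    xp, const_p = _normalize_columns(values)
    xs, const_s = _normalize_columns(ranks)
    constant = const_p | const_s
    r_pearson = np.clip(xp.T @ xp, -1.0, 1.0)
    r_spearman = np.clip(xs.T @ xs, -1.0, 1.0)

    bands = matrix.band_ids
    m = len(bands)
    if n <= exact_max_n:
        perms = _permutation_matrix(n, max_perms, seed)
        p_pearson = _permutation_pvalues(xp, r_pearson, perms)
        p_spearman = _permutation_pvalues(xs, r_spearman, perms)
    else:
        p_pearson = _t_sf_pvalue(r_pearson, n)
        p_spearman = _t_sf_pvalue(r_spearman, n)

    pairs: list[CorrelationPair] = []
    for i in range(m):
        for j in range(i + 1, m):
            valid = not (constant[i] or constant[j])
            pairs.append(
                CorrelationPair(
                    band_i=bands[i],
                    band_j=bands[j],
                    rho_spearman=float(r_spearman[i, j]) if valid else float("nan"),
                    p_spearman=float(p_spearman[i, j]) if valid else 1.0,
                    rho_pearson=float(r_pearson[i, j]) if valid else float("nan"),
                    p_pearson=float(p_pearson[i, j]) if valid else 1.0,
                    n_samples=n,
                    valid=valid,
                )
            )
    return pairs


def _permutation_pvalues(xhat: np.ndarray, r_obs: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Two-sided permutation p for every column pair of ``xhat``.

    For pair (i, j) the null distribution is the correlation of column i with
    every permuted ordering of column j; the identity permutation is included
    so p is never 0.
    """
    n_perm, n = perms.shape
    m = xhat.shape[1]
    p = np.ones((m, m))
    for j in range(1, m):
        yj = xhat[:, j]
        null = yj[perms] @ xhat[:, :j]  # (n_perm, j)
        thresh = np.abs(r_obs[:j, j]) - 1e-12
        counts = (np.abs(null) >= thresh[None, :]).sum(axis=0)
        p[:j, j] = counts / n_perm
        p[j, :j] = p[:j, j]
    return p


# ---------------------------------------------------------------------------
# edge calling
# ---------------------------------------------------------------------------

def build_network(
    pairs: list[CorrelationPair],
    nodes: dict[str, str],
    alpha: float = 0.05,
    edge_rule: str = "both",
    bh_correction: bool = False,
    group: str = "all",
) -> MicrobialNetwork:
    """Call edges from dual-correlation statistics.

    Default rule: an edge exists iff p_spearman < alpha AND p_pearson < alpha
    AND the two coefficients share a sign (which becomes the edge sign).
    ``edge_rule='either'`` accepts a single significant test (sign taken from
    it; discarded if both are significant with conflicting signs).
    ``bh_correction`` applies Benjamini-Hochberg to each family of p-values
    across pairs before thresholding.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    g = nx.Graph(group=group)
    for band, kingdom in nodes.items():
        g.add_node(band, kingdom=kingdom)

    valid = [p for p in pairs if p.valid]
    if bh_correction and valid:
        from statsmodels.stats.multitest import multipletests

        p_s = multipletests([p.p_spearman for p in valid], method="fdr_bh")[1]
        p_p = multipletests([p.p_pearson for p in valid], method="fdr_bh")[1]
    else:
        p_s = [p.p_spearman for p in valid]
        p_p = [p.p_pearson for p in valid]

    for pair, ps, pp in zip(valid, p_s, p_p):
        sig_s, sig_p = ps < alpha, pp < alpha
        sign_s = int(np.sign(pair.rho_spearman))
        sign_p = int(np.sign(pair.rho_pearson))
        if edge_rule == "both":
            if not (sig_s and sig_p and sign_s == sign_p and sign_s != 0):
                continue
            sign = sign_s
        elif edge_rule == "either":
            if sig_s and sig_p:
                if sign_s != sign_p:
                    continue
                sign = sign_s
            elif sig_s:
                sign = sign_s
            elif sig_p:
                sign = sign_p
            else:
                continue
            if sign == 0:
                continue
        else:
            raise ValueError(f"unknown edge rule {edge_rule!r}")
        if pair.band_i not in g or pair.band_j not in g:
            raise ValidationError("edge references a band outside the node set")
        g.add_edge(
            pair.band_i,
            pair.band_j,
            sign=sign,
            rho_spearman=pair.rho_spearman,
            p_spearman=float(ps),
            rho_pearson=pair.rho_pearson,
            p_pearson=float(pp),
        )
    return MicrobialNetwork(g, group=group)


def classify_edges(network: MicrobialNetwork) -> EdgeClassCounts:
    """Edge counts by endpoint kingdoms and by sign."""
    g = network.graph
    bb = ff = bf = pos = neg = 0
    for u, v, attrs in g.edges(data=True):
        ku, kv = g.nodes[u].get("kingdom"), g.nodes[v].get("kingdom")
        if ku is None or kv is None:
            raise ValidationError(f"unlabelled node on edge ({u}, {v})")
        if ku == kv == "bacteria":
            bb += 1
        elif ku == kv == "fungi":
            ff += 1
        else:
            bf += 1
        if attrs["sign"] > 0:
            pos += 1
        else:
            neg += 1
    return EdgeClassCounts(bb=bb, ff=ff, bf=bf, positives=pos, negatives=neg)


# ---------------------------------------------------------------------------
# communities & topology
# ---------------------------------------------------------------------------

def detect_communities(
    network: MicrobialNetwork, seed: int = 0, spins: int = 25
) -> tuple[dict[str, int], float | None]:
    """Spinglass partition of the interacting subgraph.

    The algorithm requires a connected graph, so it runs per connected
    component; components of fewer than 3 nodes become single communities.
    Isolated (degree-0) nodes are left out of the partition.  Returns the
    node -> community mapping and the Newman-Girvan modularity of the
    partition on the interacting subgraph (None when there are no edges).
    """
    g = network.graph
    interacting = network.interacting_nodes()
    if not interacting:
        return {}, None
    sub = g.subgraph(interacting)
    partition: dict[str, int] = {}
    next_community = 0
    for component in sorted(nx.connected_components(sub), key=lambda c: (-len(c), sorted(c)[0])):
        nodes = sorted(component)
        if len(nodes) < 3:
            for n in nodes:
                partition[n] = next_community
            next_community += 1
            continue
        comp = sub.subgraph(nodes)
        ig.set_random_number_generator(random.Random(seed))
        h = ig.Graph(
            n=len(nodes),
            edges=[(nodes.index(u), nodes.index(v)) for u, v in comp.edges()],
        )
        clustering = h.community_spinglass(spins=min(spins, len(nodes)))
        for local, community in enumerate(clustering.membership):
            partition[nodes[local]] = next_community + community
        next_community += len(set(clustering.membership))

    communities = {}
    for node, c in partition.items():
        communities.setdefault(c, set()).add(node)
    mod = float(nx_modularity(sub, list(communities.values())))
    return partition, mod


def topology_report(
    network: MicrobialNetwork,
    partition: dict[str, int] | None = None,
    modularity: float | None = None,
    config: AnalysisConfig | None = None,
    seed: int = 0,
) -> TopologyReport:
    """Compute the full topology summary of one group network.

    Average path length and clustering are averaged over the largest
    connected component; the diameter is the maximum finite shortest path in
    the graph.
    """
    if partition is None:
        partition, modularity = detect_communities(network, seed=seed)
    g = network.graph
    counts = classify_edges(network)
    interacting = network.interacting_nodes()
    n_int = len(interacting)
    n_tot = network.n_nodes
    e = network.n_edges
    kingdoms = [g.nodes[n]["kingdom"] for n in interacting]
    pct_bact = 100.0 * kingdoms.count("bacteria") / n_int if n_int else 0.0
    pct_fungi = 100.0 * kingdoms.count("fungi") / n_int if n_int else 0.0

    if e and counts.negatives:
        ratio = counts.positives / counts.negatives
    elif e:
        ratio = float("inf")
    else:
        ratio = float("nan")

    # both conventions divide by ordered (directed) node pairs, once over the
    # full band panel and once over interacting nodes only
    density_total = e / (n_tot * (n_tot - 1)) if n_tot > 1 else 0.0
    density_int = e / (n_int * (n_int - 1)) if n_int > 1 else 0.0

    if n_int:
        sub = g.subgraph(interacting)
        components = list(nx.connected_components(sub))
        lcc = sub.subgraph(max(components, key=len))
        avg_clust = float(nx.average_clustering(lcc))
        avg_path = float(nx.average_shortest_path_length(lcc)) if lcc.number_of_nodes() > 1 else 0.0
        diameter = max(
            nx.diameter(sub.subgraph(c)) for c in components
        )
    else:
        avg_clust, avg_path, diameter = 0.0, 0.0, 0

    n_comm = len(set(partition.values())) if partition else 0
    return TopologyReport(
        group=network.group,
        total_nodes=n_tot,
        interacting_nodes=n_int,
        pct_bacteria_nodes=pct_bact,
        pct_fungi_nodes=pct_fungi,
        total_edges=e,
        positives=counts.positives,
        negatives=counts.negatives,
        pos_neg_ratio=ratio,
        bb=counts.bb,
        ff=counts.ff,
        bf=counts.bf,
        avg_degree_2e_n=2 * e / n_int if n_int else 0.0,
        avg_degree_e_n=e / n_int if n_int else 0.0,
        density_total_directed=density_total,
        density_interacting_directed=density_int,
        n_communities=n_comm,
        modularity=modularity,
        avg_clustering=avg_clust,
        avg_path_length=avg_path,
        diameter=int(diameter),
    )


# ---------------------------------------------------------------------------
# model / results wrappers
# ---------------------------------------------------------------------------

class NetworkResults:
    """Fitted co-occurrence network with its partition and topology report."""

    def __init__(
        self,
        network: MicrobialNetwork,
        pairs: list[CorrelationPair],
        partition: dict[str, int],
        modularity: float | None,
        report: TopologyReport,
    ):
        self.network = network
        self.pairs = pairs
        self.partition = partition
        self.modularity = modularity
        self.report = report

    def edge_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.network.graph.edges()}

    def summary(self) -> str:
        r = self.report
        mod = f"{r.modularity:.3f}" if r.modularity is not None else "n/a"
        return (
            f"Co-occurrence network [{r.group}]\n"
            f"  nodes: {r.total_nodes} total, {r.interacting_nodes} interacting "
            f"({r.pct_bacteria_nodes:.1f}% bacteria, {r.pct_fungi_nodes:.1f}% fungi)\n"
            f"  edges: {r.total_edges} "
            f"(+{r.positives}/-{r.negatives}, ratio {r.pos_neg_ratio:.2f}; "
            f"bb {r.bb}, ff {r.ff}, bf {r.bf})\n"
            f"  avg degree 2E/N {r.avg_degree_2e_n:.2f} (E/N {r.avg_degree_e_n:.2f}); "
            f"density {r.density_total_directed:.3f} (interacting {r.density_interacting_directed:.3f})\n"
            f"  communities: {r.n_communities}, modularity {mod}, "
            f"clustering {r.avg_clustering:.3f}, path length {r.avg_path_length:.2f}, "
            f"diameter {r.diameter}"
        )


class CooccurrenceModel:
    """Dual-correlation co-occurrence network model for one band matrix.

    ``fit`` runs correlation -> edge calling -> spinglass communities ->
    topology in one pass and returns a :class:`NetworkResults`.
    """

    def __init__(
        self,
        matrix: BandMatrix,
        config: AnalysisConfig | None = None,
        group: str = "all",
    ):
        self.matrix = matrix
        self.config = config or AnalysisConfig()
        self.group = group

    def fit(self, seed: int = 0) -> NetworkResults:
        cfg = self.config
        pairs = correlate_pairs(self.matrix, binarize=cfg.binarize, seed=seed)
        network = build_network(
            pairs,
            {b: self.matrix.kingdom[b] for b in self.matrix.band_ids},
            alpha=cfg.edge_alpha,
            edge_rule=cfg.edge_rule,
            bh_correction=cfg.bh_correction,
            group=self.group,
        )
        partition, modularity = detect_communities(network, seed=seed)
        report = topology_report(network, partition, modularity, cfg)
        return NetworkResults(network, pairs, partition, modularity, report)


def infer_networks_by_group(
    matrix: BandMatrix,
    samples: SampleTable,
    config: AnalysisConfig | None = None,
    seed: int = 0,
) -> dict[str, NetworkResults]:
    """One network per treatment group, on the globally filtered band panel.

    The frequency filter is applied once across all samples so every group
    network shares the same total node panel; ``config.group_by`` picks the
    factor (``source`` pools both inoculum levels, ``inoculum`` pools all
    sources).
    """
    from .community import filter_low_frequency

    cfg = config or AnalysisConfig()
    filtered = filter_low_frequency(matrix, cfg.min_band_frequency)
    results = {}
    groups = samples.table.groupby(cfg.group_by, sort=False, observed=True)
    for name, sub in groups:
        label = str(name) if cfg.group_by == "source" else ("+inoculum" if name else "-inoculum")
        sub_matrix = filtered.subset_samples(list(sub.index))
        model = CooccurrenceModel(sub_matrix, cfg, group=label)
        results[label] = model.fit(seed=seed)
    return results
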