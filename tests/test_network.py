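"""Dual-correlation edge calling, communities and topology metrics."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import phosnet as pn
from phosnet.data import BandMatrix, ValidationError
from phosnet.network import build_network, classify_edges, detect_communities, topology_report

from conftest import toy_network


def _bm(columns: dict, kingdoms=None):
    df = pd.DataFrame({k: np.asarray(v, float) for k, v in columns.items()})
    df.index = [f"s{i}" for i in range(len(df))]
    kingdoms = kingdoms or {k: "bacteria" for k in columns}
    return BandMatrix(df, kingdoms)


def _pair(pairs, a, b):
    return next(p for p in pairs if {p.band_i, p.band_j} == {a, b})


class TestCorrelatePairs:
    def test_scaled_band_has_unit_correlations(self):
        bm = _bm({"x": [1, 2, 3, 4, 5, 7, 9, 11], "y": [2, 4, 6, 8, 10, 14, 18, 22]})
        p = pn.correlate_pairs(bm)[0]
        assert p.rho_spearman == pytest.approx(1.0)
        assert p.rho_pearson == pytest.approx(1.0)

    def test_constant_band_pairs_are_invalid(self):
        bm = _bm({"x": [1, 2, 3, 4, 5, 6, 7, 8], "c": [5] * 8, "z": [3, 1, 4, 1, 5, 9, 2, 6]})
        pairs = pn.correlate_pairs(bm)
        assert not _pair(pairs, "x", "c").valid
        assert not _pair(pairs, "c", "z").valid
        assert _pair(pairs, "x", "z").valid

    def test_exact_permutation_p_matches_bruteforce_enumeration(self):
        """Independent oracle: direct enumeration of all 7! orderings."""
        rng = np.random.default_rng(12)
        x = rng.random(7)
        y = rng.random(7)
        bm = _bm({"x": x, "y": y})
        pair = pn.correlate_pairs(bm)[0]
        obs = abs(np.corrcoef(x, y)[0, 1])
        count = sum(
            abs(np.corrcoef(x, perm)[0, 1]) >= obs - 1e-12
            for perm in itertools.permutations(y)
        )
        assert pair.p_pearson == pytest.approx(count / 5040, abs=1e-12)

    def test_analytic_p_close_to_exact_for_moderate_pair(self):
        from phosnet.network import _t_sf_pvalue

        rng = np.random.default_rng(0)
        x = np.exp(rng.standard_normal(8))
        y = np.exp(rng.standard_normal(8))
        pair = pn.correlate_pairs(_bm({"x": x, "y": y}), seed=0)[0]
        approx = _t_sf_pvalue(np.array([[pair.rho_spearman]]), 8)[0, 0]
        assert pair.p_spearman == pytest.approx(approx, abs=0.02)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError, match="4 samples"):
            pn.correlate_pairs(_bm({"x": [1, 2, 3], "y": [3, 2, 1]}))


class TestBuildNetwork:
    NODES = {"a": "bacteria", "b": "fungi"}

    def _pair(self, ps, pp, rs=0.9, rp=0.8):
        return pn.CorrelationPair("a", "b", rs, ps, rp, pp, 8)

    def test_doubly_significant_positive_pair_becomes_positive_edge(self):
        net = build_network([self._pair(0.002, 0.007)], self.NODES)
        assert net.graph["a"]["b"]["sign"] == 1

    def test_single_significant_test_is_not_enough(self):
        net = build_network([self._pair(0.002, 0.2)], self.NODES)
        assert net.n_edges == 0

    def test_sign_conflict_blocks_edge(self):
        pair = pn.CorrelationPair("a", "b", 0.9, 0.002, -0.8, 0.007, 8)
        net = build_network([pair], self.NODES)
        assert net.n_edges == 0

    def test_either_rule_keeps_singly_significant_edge(self):
        net = build_network([self._pair(0.002, 0.2)], self.NODES, edge_rule="either")
        assert net.graph["a"]["b"]["sign"] == 1

    def test_isolated_nodes_are_kept(self):
        nodes = {"a": "bacteria", "b": "fungi", "lonely": "fungi"}
        net = build_network([self._pair(0.002, 0.007)], nodes)
        assert net.n_nodes == 3
        assert set(net.interacting_nodes()) == {"a", "b"}

    def test_empty_pair_list_gives_empty_network(self):
        net = build_network([], self.NODES)
        assert net.n_edges == 0 and net.n_nodes == 2

    def test_edges_monotone_in_alpha(self, fixture_network):
        """Raising alpha never removes an edge."""
        pairs = fixture_network.pairs
        nodes = {n: d["kingdom"] for n, d in fixture_network.network.graph.nodes(data=True)}
        previous = set()
        for alpha in (0.001, 0.01, 0.05, 0.2, 0.5):
            edges = build_network(pairs, nodes, alpha=alpha)
            current = {tuple(sorted(e)) for e in edges.graph.edges()}
            assert previous <= current
            previous = current


class TestClassifyEdges:
    def test_all_bacteria_network_has_no_fungal_classes(self):
        net = toy_network(
            [("a", "b", 1), ("b", "c", -1)],
            {"a": "bacteria", "b": "bacteria", "c": "bacteria"},
        )
        counts = classify_edges(net)
        assert (counts.ff, counts.bf) == (0, 0)
        assert counts.total == 2 == counts.positives + counts.negatives

    def test_counts_match_planted_fixture_classes(self, fixture_study, fixture_network):
        _, _, _, truth = fixture_study
        counts = classify_edges(fixture_network.network)
        kingdom = fixture_network.network.graph.nodes
        expected = {"bb": 0, "ff": 0, "bf": 0}
        for e in truth.edges:
            ks = {kingdom[e.band_i]["kingdom"], kingdom[e.band_j]["kingdom"]}
            key = "bb" if ks == {"bacteria"} else ("ff" if ks == {"fungi"} else "bf")
            expected[key] += 1
        assert (counts.bb, counts.ff, counts.bf) == tuple(expected.values())

    def test_unlabelled_node_rejected(self):
        g = nx.Graph()
        g.add_node("a", kingdom="bacteria")
        g.add_node("b")
        g.add_edge("a", "b", sign=1)
        with pytest.raises(ValidationError, match="unlabelled"):
            classify_edges(pn.MicrobialNetwork(g))


def brute_force_modularity(graph, partition):
    """Independent Newman-Girvan evaluator: sum over communities of
    e_c/m - (d_c/2m)^2."""
    m = graph.number_of_edges()
    communities = {}
    for node, c in partition.items():
        communities.setdefault(c, set()).add(node)
    q = 0.0
    for nodes in communities.values():
        within = sum(1 for u, v in graph.edges() if u in nodes and v in nodes)
        degree = sum(d for _, d in graph.degree(nodes))
        q += within / m - (degree / (2 * m)) ** 2
    return q


def all_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [block + [first]] + smaller[i + 1:]
        yield smaller + [[first]]


class TestCommunities:
    def two_cliques(self):
        edges = []
        for base in (0, 4):
            for i, j in itertools.combinations(range(4), 2):
                edges.append((f"n{base + i}", f"n{base + j}", 1))
        edges.append(("n0", "n4", 1))
        kingdoms = {f"n{i}": ("bacteria" if i < 4 else "fungi") for i in range(8)}
        return toy_network(edges, kingdoms)

    def test_two_cliques_split_at_global_modularity_optimum(self):
        net = self.two_cliques()
        partition, mod = detect_communities(net, seed=3)
        assert len(set(partition.values())) == 2
        best = max(
            brute_force_modularity(
                net.graph, {n: i for i, block in enumerate(p) for n in block}
            )
            for p in all_partitions(sorted(net.graph.nodes()))
        )
        assert mod == pytest.approx(best, abs=1e-12)

    def test_complete_graph_is_one_community(self):
        g = nx.complete_graph(6)
        g = nx.relabel_nodes(g, {i: f"m{i}" for i in range(6)})
        for u, v in g.edges():
            g[u][v]["sign"] = 1
        for n in g.nodes():
            g.nodes[n]["kingdom"] = "bacteria"
        partition, mod = detect_communities(pn.MicrobialNetwork(g), seed=1)
        assert len(set(partition.values())) == 1
        assert mod <= 0.0 + 1e-12

    def test_same_seed_same_partition(self, fixture_network):
        p1, m1 = detect_communities(fixture_network.network, seed=42)
        p2, m2 = detect_communities(fixture_network.network, seed=42)
        assert p1 == p2 and m1 == m2

    def test_reported_modularity_matches_brute_force_evaluator(self, fixture_network):
        partition, mod = detect_communities(fixture_network.network, seed=7)
        interacting = fixture_network.network.graph.subgraph(
            fixture_network.network.interacting_nodes()
        )
        assert mod == pytest.approx(brute_force_modularity(interacting, partition), abs=1e-12)

    def test_empty_network_has_null_modularity(self):
        net = build_network([], {"a": "bacteria"})
        partition, mod = detect_communities(net, seed=0)
        assert partition == {} and mod is None


class TestTopologyReport:
    def test_path_graph_distances(self):
        net = toy_network(
            [("a", "b", 1), ("b", "c", 1)],
            {"a": "bacteria", "b": "bacteria", "c": "bacteria"},
        )
        report = topology_report(net, seed=0)
        assert report.avg_path_length == pytest.approx(4 / 3)
        assert report.diameter == 2

    def test_triangle_clustering_is_one(self):
        net = toy_network(
            [("a", "b", 1), ("b", "c", 1), ("a", "c", -1)],
            {"a": "bacteria", "b": "fungi", "c": "fungi"},
        )
        report = topology_report(net, seed=0)
        assert report.avg_clustering == pytest.approx(1.0)
        assert report.pos_neg_ratio == pytest.approx(2.0)

    def test_interacting_vs_total_nodes(self):
        net = toy_network(
            [("a", "b", 1)],
            {"a": "bacteria", "b": "fungi"},
            isolated=["iso1", "iso2"],
        )
        report = topology_report(net, seed=0)
        assert report.total_nodes == 4
        assert report.interacting_nodes == 2
        assert report.avg_degree_2e_n == pytest.approx(1.0)
        assert report.density_total_directed == pytest.approx(1 / 12)
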