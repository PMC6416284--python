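"""Filtering, Bray-Curtis, PCoA, UPGMA and PERMANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phosnet as pn
from phosnet.community import DistanceMatrix, Permanova, _gower_center
from phosnet.data import BandMatrix, ValidationError


def _bm(values, sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    df = pd.DataFrame(
        values,
        index=[f"{sample_prefix}{i}" for i in range(n)],
        columns=[f"B{j}" for j in range(m)],
    )
    return BandMatrix(df, {f"B{j}": "bacteria" for j in range(m)})


class TestFilter:
    def test_rare_band_removed(self):
        values = np.ones((32, 2))
        values[1:, 1] = 0.0  # band present in 1/32 samples
        out = pn.filter_low_frequency(_bm(values), 0.25)
        assert out.band_ids == ["B0"]

    def test_boundary_inclusive_at_exact_quarter(self):
        values = np.ones((8, 2))
        values[2:, 1] = 0.0  # present in exactly 2/8 = 25%
        out = pn.filter_low_frequency(_bm(values), 0.25)
        assert out.band_ids == ["B0", "B1"]

    def test_identity_when_all_bands_common(self, fixture_study):
        matrix, _, _, _ = fixture_study
        dense = matrix.subset_bands([b for b in matrix.band_ids if b != "b9"])
        assert pn.filter_low_frequency(dense, 0.25) == dense

    def test_empty_result_is_an_error(self):
        values = np.zeros((4, 2))
        values[0, :] = 1.0  # both bands in 1/4 samples
        with pytest.raises(ValidationError, match="every band"):
            pn.filter_low_frequency(_bm(values), 0.5)


class TestBrayCurtis:
    def test_identical_rows_give_zero(self):
        d = pn.bray_curtis(_bm([[1, 2, 3], [1, 2, 3]]), normalize=False)
        assert d.data[0, 1] == pytest.approx(0.0)

    def test_disjoint_support_gives_one(self):
        d = pn.bray_curtis(_bm([[1, 0, 2], [0, 3, 0]]), normalize=False)
        assert d.data[0, 1] == pytest.approx(1.0)

    def test_formula_example(self):
        # 1 - 2*min_sum/(sum_x+sum_y) = 1 - 2*2/9
        d = pn.bray_curtis(_bm([[1, 2, 0], [0, 2, 4]]), normalize=False)
        assert d.data[0, 1] == pytest.approx(1 - 4 / 9, abs=1e-10)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValidationError, match="all-zero"):
            pn.bray_curtis(_bm([[1, 2], [0, 0]]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_to_band_order(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.random((5, 7))
        perm = rng.permutation(7)
        d1 = pn.bray_curtis(_bm(values))
        d2 = pn.bray_curtis(_bm(values[:, perm]))
        np.testing.assert_allclose(d1.data, d2.data, atol=1e-12)


class TestPcoa:
    def test_two_samples_embed_at_plus_minus_half_distance(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.6], [0.6, 0.0]]))
        ordn = pn.pcoa(dm, k=1)
        coords = np.sort(ordn.coordinates["PCo1"].to_numpy())
        np.testing.assert_allclose(coords, [-0.3, 0.3], atol=1e-12)

    def test_collinear_points_recovered_on_first_axis(self):
        pts = np.array([0.0, 1.0, 3.0])
        d = np.abs(pts[:, None] - pts[None, :])
        ordn = pn.pcoa(DistanceMatrix(["a", "b", "c"], d))
        axis1 = ordn.coordinates["PCo1"].to_numpy()
        gaps = np.diff(np.sort(axis1))
        # spacing matches the input up to axis sign (which reverses the gaps)
        np.testing.assert_allclose(np.sort(gaps), [1.0, 2.0], atol=1e-9)
        assert ordn.eigenvalues[1] == pytest.approx(0.0, abs=1e-9)

    def test_planar_configuration_reproduced(self):
        rng = np.random.default_rng(5)
        pts = rng.random((6, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ordn = pn.pcoa(DistanceMatrix([f"s{i}" for i in range(6)], d), k=2)
        coords = ordn.coordinates.to_numpy()
        d2 = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(d2, d, atol=1e-9)

    def test_matches_scikit_bio(self, fixture_study):
        """Independent oracle: scikit-bio's PCoA on the fixture distances."""
        import skbio

        matrix, _, _, _ = fixture_study
        dist = pn.bray_curtis(pn.filter_low_frequency(matrix))
        ours = pn.pcoa(dist, k=2)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dist.data, ids=dist.sample_ids), method="eigh"
        )
        for axis in range(2):
            a = ours.coordinates.iloc[:, axis].to_numpy()
            b = ref.samples.iloc[:, axis].to_numpy()
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8
        np.testing.assert_allclose(
            ours.proportion_explained[:2], ref.proportion_explained[:2], atol=1e-8
        )

    def test_requesting_too_many_axes_warns_and_reduces(self):
        pts = np.array([0.0, 1.0, 3.0])  # collinear: one positive eigenvalue
        d = np.abs(pts[:, None] - pts[None, :])
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            ordn = pn.pcoa(DistanceMatrix(["a", "b", "c"], d), k=2)
        assert ordn.coordinates.shape[1] == 1


class TestUpgma:
    def test_closest_pair_merges_first(self):
        d = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0]], dtype=float)
        dend = pn.upgma(DistanceMatrix(["A", "B", "C"], d))
        i, j, h, _ = dend.merges[0]
        assert {i, j} == {0, 1} and h == pytest.approx(1.0)

    def test_ultrametric_input_reproduced_by_cophenetic(self):
        # perfect ultrametric on 4 leaves
        d = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]], dtype=float
        )
        dend = pn.upgma(DistanceMatrix(list("abcd"), d))
        np.testing.assert_allclose(dend.cophenetic().data, d, atol=1e-12)

    def test_matches_scipy_cophenet(self):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(8)
        pts = rng.random((7, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dend = pn.upgma(DistanceMatrix([f"s{i}" for i in range(7)], d))
        ref = squareform(cophenet(linkage(squareform(d), method="average")))
        np.testing.assert_allclose(dend.cophenetic().data, ref, atol=1e-10)

    def test_tie_broken_toward_lowest_index_pair(self):
        d = np.full((4, 4), 5.0)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 1.0
        d[2, 3] = d[3, 2] = 1.0  # tied with (0,1)
        dend = pn.upgma(DistanceMatrix(list("abcd"), d))
        assert dend.merges[0][:2] == (0, 1)

    def test_newick_parses_with_dendropy(self, fixture_study):
        import dendropy

        matrix, _, _, _ = fixture_study
        dend = pn.upgma(pn.bray_curtis(pn.filter_low_frequency(matrix)))
        tree = dendropy.Tree.get(data=dend.to_newick(), schema="newick")
        assert len(tree.leaf_nodes()) == 8


class TestPermanova:
    def test_r2_partition_sums_to_one(self, default_study):
        matrix, samples, _, _ = default_study
        dist = pn.bray_curtis(pn.filter_low_frequency(matrix))
        res = pn.permanova(dist, samples, ("source", "inoculum"), n_perm=99, seed=0)
        r2 = res.table.loc[["source", "inoculum", "Residual"], "R2"].sum()
        assert r2 == pytest.approx(1.0, abs=1e-10)

    def test_invariant_to_joint_sample_reordering(self, default_study):
        matrix, samples, _, _ = default_study
        filtered = pn.filter_low_frequency(matrix)
        rng = np.random.default_rng(0)
        order = list(rng.permutation(filtered.sample_ids))
        d1 = pn.bray_curtis(filtered)
        d2 = pn.bray_curtis(filtered.subset_samples(order))
        f1 = Permanova(d1, samples).fit(9, seed=1).table["F"]
        f2 = Permanova(d2, samples).fit(9, seed=1).table["F"]
        pd.testing.assert_series_equal(f1, f2, atol=1e-9, rtol=0)

    def test_single_level_factor_rejected(self, fixture_study):
        matrix, samples, _, _ = fixture_study
        st_ = samples.table.copy()
        st_["inoculum"] = True
        dist = pn.bray_curtis(pn.filter_low_frequency(matrix))
        with pytest.raises(ValidationError, match="single level"):
            Permanova(dist, st_, ("source", "inoculum"))

    def test_matches_scikit_bio_one_way(self, default_study):
        """Independent oracle: scikit-bio's one-way PERMANOVA pseudo-F."""
        import skbio

        matrix, samples, _, _ = default_study
        dist = pn.bray_curtis(pn.filter_low_frequency(matrix))
        ours = Permanova(dist, samples, ["source"]).fit(99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dist.data, ids=dist.sample_ids),
            samples.table["source"].to_numpy(),
            permutations=99,
        )
        assert ours.table.loc["source", "F"] == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_source_effect_dominates_inoculum(self):
        """With a planted source shift and no inoculum shift, the source term
        explains more variance than inoculum in >= 95% of 100 seeded runs."""
        from phosnet.config import SyntheticConfig

        cfg = SyntheticConfig(n_bacteria_bands=12, n_fungi_bands=8, planted_edges=())
        wins = 0
        for seed in range(100):
            matrix, samples, _, _ = pn.generate_study(cfg, seed=seed)
            dist = pn.bray_curtis(pn.filter_low_frequency(matrix))
            res = Permanova(dist, samples).fit(9, seed=seed)
            wins += res.table.loc["source", "R2"] > res.table.loc["inoculum", "R2"]
        assert wins >= 95
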