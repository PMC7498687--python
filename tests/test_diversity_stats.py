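"""Formula-level statistics against hand values and independent oracles."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.special import comb

from obulink import (
    CountMatrix,
    DistanceMatrix,
    anova_tukey,
    biplot_loadings,
    bray_curtis,
    chao1,
    normalize,
    pcoa,
    permanova,
    rarefaction_curve,
    richness_per_sample,
)


class TestChao1:
    def test_no_rare_features(self):
        r = chao1([5, 5, 5])
        assert r.chao1 == 3 and r.observed_s == 3 and r.chao1_se == 0

    def test_hand_computed_bias_corrected(self):
        # f1=2, f2=2: 5 + 2*1/(2*3)
        r = chao1([1, 1, 2, 2, 3])
        assert r.chao1 == pytest.approx(5 + 2 * 1 / (2 * 3))

    def test_classic_variant(self):
        r = chao1([1, 1, 2, 2, 3], bias_corrected=False)
        assert r.chao1 == pytest.approx(5 + 4 / 4)

    def test_never_below_observed_property(self, rng):
        for _ in range(300):
            counts = rng.integers(0, 6, size=rng.integers(1, 30))
            r = chao1(counts)
            assert r.chao1 >= r.observed_s

    def test_matches_skbio_oracle(self, rng):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        for _ in range(50):
            counts = rng.integers(0, 8, size=20)
            if counts.sum() == 0:
                continue
            for bc in (True, False):
                ours = chao1(counts, bias_corrected=bc).chao1
                theirs = float(skbio_alpha.chao1(counts, bias_corrected=bc))
                assert ours == pytest.approx(theirs, rel=1e-12)

    def test_normalized_counts_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            chao1([1.5, 2.0])


class TestRarefaction:
    def test_full_depth_gives_observed(self):
        counts = [4, 3, 2, 1]
        assert rarefaction_curve(counts, [10])[0] == pytest.approx(4)

    def test_depth_one_gives_one(self):
        assert rarefaction_curve([7, 3], [1])[0] == pytest.approx(1.0)

    def test_depth_beyond_total_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            rarefaction_curve([2, 2], [5])

    def test_matches_exact_combinatorial_oracle(self):
        counts = np.array([5, 3, 2, 1, 1])
        n_total = counts.sum()
        for depth in (1, 3, 6, 9):
            expected = sum(
                1 - comb(n_total - ni, depth, exact=True) / comb(n_total, depth, exact=True)
                for ni in counts
            )
            assert rarefaction_curve(counts, [depth])[0] == pytest.approx(expected, rel=1e-12)

    def test_matches_monte_carlo_subsampling(self, rng):
        counts = rng.integers(0, 20, size=12)
        counts[0] += 1  # ensure non-empty
        n_total = int(counts.sum())
        depth = n_total // 2
        reps = 1000
        pool = np.repeat(np.arange(len(counts)), counts)
        richness = np.empty(reps)
        for r in range(reps):
            sub = rng.choice(pool, size=depth, replace=False)
            richness[r] = len(np.unique(sub))
        mc_mean, mc_se = richness.mean(), richness.std(ddof=1) / np.sqrt(reps)
        exact = rarefaction_curve(counts, [depth])[0]
        assert abs(exact - mc_mean) <= 3 * mc_se + 1e-9


class TestNormalize:
    def test_proportional_scaling(self):
        m = CountMatrix(["a", "b", "c"], ["s"], np.array([[10.0], [30.0], [60.0]]))
        out = normalize(m, 100_000)
        np.testing.assert_allclose(out.counts[:, 0], [10_000, 30_000, 60_000])
        assert out.normalized

    def test_column_sums_exact(self, toy_matrix):
        out = normalize(toy_matrix, 100_000)
        np.testing.assert_allclose(out.counts.sum(axis=0), 100_000)

    def test_rarefy_reproducible_and_exact_depth(self, rng):
        counts = rng.integers(0, 500, size=(20, 3)).astype(float) + 1
        m = CountMatrix([f"f{i}" for i in range(20)], ["a", "b", "c"], counts)
        r1 = normalize(m, 200, method="rarefy", seed=4)
        r2 = normalize(m, 200, method="rarefy", seed=4)
        np.testing.assert_array_equal(r1.counts, r2.counts)
        np.testing.assert_array_equal(r1.counts.sum(axis=0), 200)

    def test_rarefy_drops_shallow_columns_with_warning(self):
        m = CountMatrix(["a"], ["s1", "s2"], np.array([[50.0, 500.0]]))
        with pytest.warns(UserWarning, match="s1"):
            out = normalize(m, 100, method="rarefy", seed=0)
        assert out.sample_ids == ["s2"]

    def test_empty_column_rejected(self):
        m = CountMatrix(["a"], ["s1", "s2"], np.array([[0.0, 5.0]]))
        with pytest.raises(ValueError, match="s1"):
            normalize(m)


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        m = CountMatrix(["a", "b"], ["x", "y"], np.array([[3.0, 3.0], [1.0, 1.0]]))
        assert bray_curtis(m).matrix[0, 1] == 0

    def test_disjoint_supports_one(self):
        m = CountMatrix(["a", "b"], ["x", "y"], np.array([[3.0, 0.0], [0.0, 2.0]]))
        assert bray_curtis(m).matrix[0, 1] == 1

    def test_hand_computed(self):
        m = CountMatrix(
            ["a", "b", "c"], ["x", "y"], np.array([[6.0, 2.0], [0.0, 2.0], [2.0, 0.0]])
        )
        assert bray_curtis(m).matrix[0, 1] == pytest.approx(1 - 2 * 2 / 12)

    def test_matches_scipy_oracle(self, rng):
        counts = rng.integers(0, 40, size=(10, 5)).astype(float)
        counts[0] += 1
        m = CountMatrix([f"f{i}" for i in range(10)], [f"s{j}" for j in range(5)], counts)
        d = bray_curtis(m).matrix
        for i, j in itertools.combinations(range(5), 2):
            assert d[i, j] == pytest.approx(
                scipy_braycurtis(counts[:, i], counts[:, j]), rel=1e-12
            )

    def test_joint_rescaling_invariance(self, rng):
        counts = rng.integers(1, 40, size=(8, 3)).astype(float)
        ids = [f"f{i}" for i in range(8)]
        m1 = CountMatrix(ids, ["a", "b", "c"], counts)
        m2 = CountMatrix(ids, ["a", "b", "c"], counts * 7, normalized=True)
        np.testing.assert_allclose(bray_curtis(m1).matrix, bray_curtis(m2).matrix)

    def test_zero_total_sample_rejected(self):
        m = CountMatrix(["a"], ["x", "y"], np.array([[0.0, 5.0]]))
        with pytest.raises(ValueError, match="zero total"):
            bray_curtis(m)


class TestPcoa:
    def test_planar_points_reconstructed(self, rng):
        pts = rng.normal(size=(6, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(6)], d))
        assert int((res.eigenvalues > 1e-8).sum()) == 2
        coords = res.coordinates
        d_rec = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(d_rec, d, atol=1e-8)

    def test_all_zero_distances(self):
        res = pcoa(DistanceMatrix(["a", "b", "c"], np.zeros((3, 3))))
        assert res.coordinates.shape[1] == 0
        np.testing.assert_allclose(res.eigenvalues, 0, atol=1e-12)

    def test_eigenvalue_sum_equals_trace(self, rng):
        pts = rng.normal(size=(5, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(5)], d))
        n = 5
        a = -0.5 * d**2
        h = np.eye(n) - np.ones((n, n)) / n
        assert res.eigenvalues.sum() == pytest.approx(np.trace(h @ a @ h), abs=1e-9)

    def test_matches_skbio_coordinates(self, rng):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        skbio_dm = pytest.importorskip("skbio.stats.distance")
        pts = rng.normal(size=(7, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ours = pcoa(DistanceMatrix([f"s{i}" for i in range(7)], d))
        theirs = skbio_ord.pcoa(skbio_dm.DistanceMatrix(d))
        k = ours.coordinates.shape[1]
        for ax in range(k):
            ref = theirs.samples.values[:, ax]
            got = ours.coordinates[:, ax]
            sign = np.sign(np.dot(ref, got)) or 1.0
            np.testing.assert_allclose(got, sign * ref, atol=1e-8)


class TestBiplotLoadings:
    def make(self, rng):
        pts = rng.normal(size=(8, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ordn = pcoa(DistanceMatrix([f"s{i}" for i in range(8)], d))
        return ordn

    def test_feature_equal_to_axis_loads_maximally(self, rng):
        ordn = self.make(rng)
        feat = ordn.coordinates[:, 0] - ordn.coordinates[:, 0].min()
        m = CountMatrix(["f"], ordn.sample_ids, feat[None, :], normalized=True)
        res = biplot_loadings(m, ordn)
        vec = res["loadings"]["f"]
        assert abs(vec[0]) == pytest.approx(1.0)
        assert abs(vec[1]) < 0.2
        assert res["flagged"] == ["f"]

    def test_constant_feature_zero(self, rng):
        ordn = self.make(rng)
        m = CountMatrix(
            ["f"], ordn.sample_ids, np.full((1, 8), 3.0), normalized=True
        )
        res = biplot_loadings(m, ordn)
        np.testing.assert_array_equal(res["loadings"]["f"], 0)

    def test_axis_negation_negates_loadings(self, rng):
        ordn = self.make(rng)
        feat = rng.random(8) * 5
        m = CountMatrix(["f"], ordn.sample_ids, feat[None, :], normalized=True)
        before = biplot_loadings(m, ordn)["loadings"]["f"].copy()
        ordn.coordinates[:, 1] *= -1
        after = biplot_loadings(m, ordn)["loadings"]["f"]
        assert after[1] == pytest.approx(-before[1])
        assert after[0] == pytest.approx(before[0])


def brute_force_pseudo_f(d, labels):
    """Independent PERMANOVA pseudo-F: explicit double loops over pairs."""
    n = len(labels)
    groups = sorted(set(labels))
    sst = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ssw = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ssw += sum(
            d[i, j] ** 2 for ii, i in enumerate(idx) for j in idx[ii + 1:]
        ) / len(idx)
    a = len(groups)
    return ((sst - ssw) / (a - 1)) / (ssw / (n - a))


class TestPermanova:
    def make_dist(self, rng, n=8, shift=0.0):
        pts = rng.normal(size=(n, 3))
        pts[n // 2:, 0] += shift
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        return DistanceMatrix([f"s{i}" for i in range(n)], d)

    def test_f_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            dist = self.make_dist(rng)
            labels = ["a"] * 4 + ["b"] * 4
            res = permanova(dist, labels, n_perm=9, seed=1)
            assert res.pseudo_f == pytest.approx(
                brute_force_pseudo_f(dist.matrix, labels), rel=1e-12
            )

    def test_f_matches_skbio(self, rng):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        dist = self.make_dist(rng)
        labels = ["a"] * 4 + ["b"] * 4
        res = permanova(dist, labels, n_perm=9, seed=1)
        theirs = skbio_dist.permanova(
            skbio_dist.DistanceMatrix(dist.matrix), grouping=labels, permutations=9
        )
        assert res.pseudo_f == pytest.approx(float(theirs["test statistic"]), rel=1e-10)

    def test_complete_separation_minimum_p(self, rng):
        # widely separated groups: only a permutation reproducing the exact
        # partition can tie F_obs, so with a fixed seed p hits its floor
        dist = self.make_dist(rng, n=12, shift=100.0)
        res = permanova(dist, ["a"] * 6 + ["b"] * 6, n_perm=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_exhaustive_small_case(self, rng):
        # all label permutations for N=6: permutation p upper-bounds the
        # exhaustive tail probability and F matches the oracle
        dist = self.make_dist(rng, n=6, shift=2.0)
        labels = ["a", "a", "a", "b", "b", "b"]
        f_obs = permanova(dist, labels, n_perm=999, seed=3).pseudo_f
        f_all = [
            brute_force_pseudo_f(dist.matrix, perm)
            for perm in set(itertools.permutations(labels))
        ]
        assert f_obs == pytest.approx(brute_force_pseudo_f(dist.matrix, labels))
        assert max(f_all) >= f_obs

    def test_group_of_one_rejected(self, rng):
        dist = self.make_dist(rng, n=5)
        with pytest.raises(ValueError, match="size 1"):
            permanova(dist, ["a"] * 4 + ["b"], n_perm=9)


class TestAnovaTukey:
    def test_identical_means_share_letter(self):
        res = anova_tukey({"g1": [1, 2, 3], "g2": [1, 2, 3], "g3": [2, 1, 3]})
        assert res["f"] == pytest.approx(0.0, abs=1e-12)
        letters = set(res["letters"].values())
        assert len(letters) == 1

    def test_two_group_f_equals_t_squared(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 6.0, 8.0]
        from scipy import stats as ss

        res = anova_tukey({"a": a, "b": b})
        t, _ = ss.ttest_ind(a, b)
        assert res["f"] == pytest.approx(t**2, rel=1e-12)

    def test_tukey_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multicomp")
        groups = {"a": [1.0, 2.0, 1.5], "b": [4.0, 5.0, 4.5], "c": [1.2, 2.2, 1.4]}
        res = anova_tukey(groups)
        data = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), 3)
        tk = sm.pairwise_tukeyhsd(data, labels)
        # statsmodels orders pairs (a,b), (a,c), (b,c)
        pvals = tk.pvalues
        ours = [res["pairwise_p"][("a", "b")], res["pairwise_p"][("a", "c")],
                res["pairwise_p"][("b", "c")]]
        np.testing.assert_allclose(ours, pvals, atol=1e-6)

    def test_separated_groups_get_distinct_letters(self):
        res = anova_tukey({"lo": [1.0, 1.1, 0.9], "hi": [9.0, 9.1, 8.9]})
        assert res["letters"]["lo"] != res["letters"]["hi"]

    def test_all_constant_groups_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            anova_tukey({"a": [1.0, 1.0], "b": [2.0, 2.0]})


def test_richness_per_sample_rejects_normalized(toy_matrix):
    norm = normalize(toy_matrix, 1000)
    with pytest.raises(ValueError, match="normalized"):
        richness_per_sample(norm)
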