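"""Diversity statistics against enumeration oracles and reference libraries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.stats import ttest_1samp, ttest_ind
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from cmtrack.core import AbundanceTable
from cmtrack.stats import (
    bonferroni,
    bray_curtis,
    pairwise_distances,
    pcoa,
    permanova,
    rank_sum_test,
    t_tests,
)


def make_abundance(values):
    values = np.asarray(values, dtype=float)
    values = values / values.sum(axis=1, keepdims=True)
    ids = [f"s{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=ids, columns=[f"a{j}" for j in range(values.shape[1])])
    meta = pd.DataFrame(index=df.index)
    feat = pd.DataFrame(index=df.columns)
    return AbundanceTable(values=df, samples=meta, features=feat)


def exhaustive_permanova(dm: np.ndarray, labels: list) -> tuple[float, float]:
    """Enumerate every label ordering; returns (F_obs, exact p)."""
    labels = np.asarray(labels)
    codes = np.unique(labels)
    a = len(codes)
    n = len(labels)
    d2 = dm**2
    ss_total = d2.sum() / (2 * n)

    def f_of(perm):
        ssw = 0.0
        for g in codes:
            ix = np.flatnonzero(perm == g)
            ssw += d2[np.ix_(ix, ix)].sum() / (2 * len(ix))
        ssb = ss_total - ssw
        if ssw <= 0:
            return math.inf if ssb > 0 else 0.0
        return (ssb / (a - 1)) / (ssw / (n - a))

    f_obs = f_of(labels)
    perms = [np.asarray(p) for p in set(itertools.permutations(labels))]
    exceed = sum(f_of(p) >= f_obs for p in perms)
    return f_obs, exceed / len(perms)


class TestBrayCurtis:
    def test_identical_vectors_have_zero_dissimilarity(self):
        assert bray_curtis([0.2, 0.8], [0.2, 0.8]) == 0.0

    def test_disjoint_supports_give_one(self):
        assert bray_curtis([1, 0], [0, 1]) == 1.0

    def test_hand_evaluated_example(self):
        assert bray_curtis([0.5, 0.5, 0.0], [0.0, 0.5, 0.5]) == pytest.approx(0.5)

    def test_all_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [1, 0])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 100, allow_nan=False), st.floats(0, 100, allow_nan=False)
            ),
            min_size=1,
            max_size=10,
        )
    )
    def test_symmetry_and_range(self, pairs):
        x = [p[0] for p in pairs]
        y = [p[1] for p in pairs]
        if sum(x) == 0 or sum(y) == 0:
            return
        d = bray_curtis(x, y)
        assert d == pytest.approx(bray_curtis(y, x))
        assert 0.0 <= d <= 1.0

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = rng.random(8) + 1e-6
            y = rng.random(8) + 1e-6
            assert bray_curtis(x, y) == pytest.approx(scipy_braycurtis(x, y))


class TestPairwiseDistances:
    def test_identical_rows_give_zero_matrix(self):
        d = pairwise_distances(make_abundance([[1, 2, 3]] * 3))
        assert np.allclose(d.data, 0.0)

    def test_disjoint_rows_give_one(self):
        d = pairwise_distances(make_abundance([[1, 0], [0, 1]]))
        assert d.data[0, 1] == 1.0

    def test_matrix_matches_scalar_recomputation(self):
        rng = np.random.default_rng(6)
        values = rng.random((5, 7)) + 1e-9
        ab = make_abundance(values)
        d = pairwise_distances(ab)
        rows = ab.values.to_numpy()
        for i in range(5):
            for j in range(5):
                expected = 0.0 if i == j else bray_curtis(rows[i], rows[j])
                assert d.data[i, j] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(d.data, d.data.T, atol=1e-12)


class TestPermanova:
    def worked_example(self):
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = 0.0
        d[2, 3] = d[3, 2] = 0.0
        return DistanceMatrix(d, ids=list("wxyz")), ["g1", "g1", "g2", "g2"]

    def test_two_tight_pairs_give_eta_one_and_exact_third(self):
        dm, groups = self.worked_example()
        f_obs, p_exact = exhaustive_permanova(dm.data, groups)
        assert math.isinf(f_obs)
        assert p_exact == pytest.approx(1 / 3)
        res = permanova(dm, groups, n_permutations=3000, seed=0)
        assert res.eta_squared == pytest.approx(1.0)
        assert math.isinf(res.pseudo_F)
        mc_se = math.sqrt(p_exact * (1 - p_exact) / 3000)
        assert abs(res.p_value - p_exact) <= 2 * mc_se + 1 / 3001

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        pts = rng.random((n, 3))
        dm = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = ["a"] * 3 + ["b"] * 3
        _, p_exact = exhaustive_permanova(dm, labels)
        res = permanova(DistanceMatrix(dm, ids=[str(i) for i in range(n)]), labels,
                        n_permutations=5000, seed=123)
        mc_se = math.sqrt(p_exact * (1 - p_exact) / 5000)
        assert abs(res.p_value - p_exact) <= 2 * mc_se + 1 / 5001

    def test_equidistant_points_have_closed_form_eta(self):
        n, sizes = 8, (3, 5)
        d = 0.7 * (np.ones((n, n)) - np.eye(n))
        labels = ["a"] * sizes[0] + ["b"] * sizes[1]
        res = permanova(DistanceMatrix(d, ids=[str(i) for i in range(n)]), labels,
                        n_permutations=500, seed=0)
        a = 2
        assert res.eta_squared == pytest.approx((a - 1) / (n - 1))
        assert res.p_value > 0.9

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(9)
        pts = rng.random((10, 4))
        dm = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        d = DistanceMatrix(dm, ids=[str(i) for i in range(10)])
        labels = ["a"] * 5 + ["b"] * 5
        r1 = permanova(d, labels, n_permutations=500, seed=77)
        r2 = permanova(d, labels, n_permutations=500, seed=77)
        assert r1.p_value == r2.p_value

    def test_pseudo_f_matches_skbio(self):
        rng = np.random.default_rng(10)
        values = rng.random((12, 6)) + 1e-9
        d = pairwise_distances(make_abundance(values))
        labels = ["a"] * 6 + ["b"] * 6
        ours = permanova(d, labels, n_permutations=999, seed=0)
        ref = skbio_permanova(d, grouping=labels, permutations=999)
        assert ours.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-9)
        assert abs(ours.p_value - ref["p-value"]) < 0.06

    def test_sum_of_squares_decomposition(self):
        rng = np.random.default_rng(13)
        values = rng.random((9, 5)) + 1e-9
        d = pairwise_distances(make_abundance(values))
        res = permanova(d, ["a"] * 4 + ["b"] * 5, n_permutations=10, seed=0)
        assert res.ss_between + res.ss_within == pytest.approx(res.ss_total, abs=1e-9)
        assert res.eta_squared == pytest.approx(res.ss_between / res.ss_total)

    def test_eta_squared_monotone_in_effect_size(self):
        """Stronger simulated group separation yields larger eta-squared."""
        effects = [0.0, 0.15, 0.3, 0.6]
        means = []
        for effect in effects:
            etas = []
            for seed in range(10):
                rng = np.random.default_rng(1000 + seed)
                base = rng.lognormal(0, 1.5, size=30)
                base /= base.sum()
                alt = rng.lognormal(0, 1.5, size=30)
                alt /= alt.sum()
                shifted = (1 - effect) * base + effect * alt
                group_a = rng.dirichlet(base * 80, size=8)
                group_b = rng.dirichlet(shifted * 80, size=8)
                d = pairwise_distances(make_abundance(np.vstack([group_a, group_b])))
                res = permanova(d, ["a"] * 8 + ["b"] * 8, n_permutations=1, seed=0)
                etas.append(res.eta_squared)
            means.append(np.mean(etas))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_single_group_rejected(self):
        d = DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
        with pytest.raises(ValueError):
            permanova(d, ["a", "a", "a"], n_permutations=10, seed=0)


class TestPcoa:
    def test_collinear_points_recover_one_axis(self):
        pos = np.array([0.0, 1.0, 2.0])
        dm = np.abs(pos[:, None] - pos[None])
        res = pcoa(DistanceMatrix(dm, ids=list("abc")), k=2)
        positive = res.eigenvalues > 1e-9
        assert positive.sum() == 1
        coords = res.coordinates.to_numpy()
        recon = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        assert np.allclose(recon, dm, atol=1e-9)
        assert res.padded

    def test_identical_samples_give_zero_embedding(self):
        res = pcoa(DistanceMatrix(np.zeros((4, 4)), ids=list("abcd")), k=2)
        assert np.allclose(res.coordinates.to_numpy(), 0.0)
        assert np.allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_euclidean_distances_reconstructed_by_all_positive_axes(self):
        rng = np.random.default_rng(21)
        pts = rng.random((6, 3))
        dm = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix(dm, ids=[str(i) for i in range(6)]), k=5)
        coords = res.coordinates.to_numpy()
        recon = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        assert np.allclose(recon, dm, atol=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(22)
        pts = rng.random((7, 4))
        dm = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(7)]
        perm = rng.permutation(7)
        res1 = pcoa(DistanceMatrix(dm, ids=ids), k=3)
        res2 = pcoa(DistanceMatrix(dm[np.ix_(perm, perm)],
                                   ids=[ids[i] for i in perm]), k=3)
        c1 = res1.coordinates.loc[[ids[i] for i in perm]].to_numpy()
        c2 = res2.coordinates.to_numpy()
        # coordinates agree up to per-axis sign
        for axis in range(3):
            col1, col2 = c1[:, axis], c2[:, axis]
            assert np.allclose(col1, col2, atol=1e-8) or np.allclose(
                col1, -col2, atol=1e-8
            )

    def test_leading_eigenvalues_match_skbio(self):
        rng = np.random.default_rng(23)
        values = rng.random((8, 5)) + 1e-9
        d = pairwise_distances(make_abundance(values))
        ours = pcoa(d, k=3)
        ref = skbio_pcoa(d, number_of_dimensions=3)
        assert np.allclose(ours.eigenvalues[:3], ref.eigvals.to_numpy()[:3], atol=1e-8)
        # ratios among the positive axes agree even though the normalizing
        # denominator differs (positive-only here vs trace in skbio)
        ref_prop = ref.proportion_explained.to_numpy()[:3]
        assert np.allclose(
            ours.proportion_explained[:3] / ours.proportion_explained[0],
            ref_prop / ref_prop[0],
            atol=1e-6,
        )


class TestRankSum:
    def test_identical_samples_not_separated(self):
        _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p >= 0.9

    def test_near_exact_for_three_vs_three(self):
        # exact two-sided p over all 20 splits of {1..6} into 3+3
        pooled = [1, 2, 3, 4, 5, 6]
        obs = sum(range(1, 4))  # ranks of x = (1,2,3)
        stats = []
        for combo in itertools.combinations(range(6), 3):
            w = sum(pooled[i] for i in combo)
            stats.append(w)
        mean_w = np.mean(stats)
        p_exact = np.mean([abs(w - mean_w) >= abs(obs - mean_w) for w in stats])
        assert p_exact == pytest.approx(0.1)
        _, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert abs(p - p_exact) <= 0.06

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(31)
        x, y = rng.random(6), rng.random(8)
        s1, p1 = rank_sum_test(x, y)
        s2, p2 = rank_sum_test(3.5 * x + 2, 3.5 * y + 2)
        assert s1 == s2 and p1 == pytest.approx(p2)

    def test_all_identical_values_give_p_one(self):
        _, p = rank_sum_test([5, 5], [5, 5, 5])
        assert p == 1.0


class TestTTests:
    def test_one_sample_at_own_mean_is_null(self):
        t, p = t_tests([1.0, 2.0, 3.0], mu0=2.0)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_identical_samples_are_null(self):
        t, p = t_tests([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_pooled_t_matches_scipy(self):
        x, y = [0, 0, 1, 1, 1], [2, 2, 3, 3, 3]
        t, p = t_tests(x, y)
        ref = ttest_ind(x, y)
        assert t == pytest.approx(ref.statistic, abs=1e-6)
        assert p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_one_sample_matches_scipy(self):
        rng = np.random.default_rng(41)
        x = rng.random(10)
        t, p = t_tests(x, mu0=0.3)
        ref = ttest_1samp(x, 0.3)
        assert t == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(42)
        x, y = rng.random(6), 2 + 3 * rng.random(9)
        t, p = t_tests(x, y, welch=True)
        ref = ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            t_tests([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(ValueError):
            t_tests([3.0, 3.0], mu0=1.0)


class TestBonferroni:
    def test_scaling_capping_and_identity(self):
        assert bonferroni([0.01, 0.04]) == [0.02, 0.08]
        assert bonferroni([0.37]) == [0.37]
        assert bonferroni([0.6, 0.9]) == [1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.5])
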