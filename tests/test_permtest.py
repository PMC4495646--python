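"""The distribution test: F statistic, median ANOVA, permutation scheme."""

import numpy as np
import pytest
from scipy import stats

from quantro import (
    DataError,
    FeatureMatrix,
    QuantroTest,
    f_quantro,
    median_anova,
)
from .conftest import random_grouped_matrix


def brute_force_f(values: np.ndarray, groups: np.ndarray) -> float:
    """Literal-sum oracle: plain Python loops over the defining formulas.

    Median-center each sample, sort it, average quantile functions within
    groups and over all samples (weighted grand mean), then evaluate the
    between/within sums of squares term by term.
    """
    X = values - np.median(values, axis=0, keepdims=True)
    qfs = {j: np.sort(X[:, j]) for j in range(X.shape[1])}
    levels = list(dict.fromkeys(groups))
    members = {lvl: [j for j in range(X.shape[1]) if groups[j] == lvl] for lvl in levels}
    n = X.shape[0]
    n_t = X.shape[1]
    K = len(levels)

    def integral(diff):
        return sum(d * d for d in diff) / n

    grand = [sum(qfs[j][r] for j in range(n_t)) / n_t for r in range(n)]
    group_mean = {
        lvl: [sum(qfs[j][r] for j in members[lvl]) / len(members[lvl]) for r in range(n)]
        for lvl in levels
    }
    ssb = 0.0
    ssw = 0.0
    for lvl in levels:
        gm = group_mean[lvl]
        ssb += len(members[lvl]) * integral([gm[r] - grand[r] for r in range(n)])
        for j in members[lvl]:
            ssw += integral([qfs[j][r] - gm[r] for r in range(n)])
    msb = ssb / (K - 1)
    msw = ssw / (n_t - K)
    if msw == 0.0:
        return float("inf") if msb > 0 else 0.0
    return msb / msw


class TestFStatistic:
    def test_worked_example(self, worked_matrix):
        res = f_quantro(worked_matrix)
        assert res.f_quantro == pytest.approx(18.0)
        assert res.df_between == 1 and res.df_within == 2

    def test_pure_location_shifts_give_zero(self):
        # g1 columns are [1,2,3]; g2 columns are shifted copies [3,4,5]
        X = np.array([[1, 1, 3, 3], [2, 2, 4, 4], [3, 3, 5, 5]], float)
        res = f_quantro(X, groups=["g1", "g1", "g2", "g2"])
        assert res.f_quantro == 0.0

    def test_all_columns_identical_gives_zero(self):
        X = np.tile(np.array([[1.0], [2.0], [7.0]]), (1, 5))
        res = f_quantro(X, groups=["a", "a", "b", "b", "b"])
        assert res.f_quantro == 0.0
        assert res.ss_total == 0.0

    def test_infinite_f_when_within_variance_vanishes(self):
        # identical columns within each group, groups differ in spread
        a = np.array([-1.0, 0.0, 2.0])
        b = 3 * a
        X = np.column_stack([a, a, b, b])
        res = f_quantro(X, groups=["a", "a", "b", "b"])
        assert np.isinf(res.f_quantro)

    def test_matches_bruteforce_oracle_on_small_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = int(rng.integers(2, 6))
            sizes = rng.integers(1, 4, size=int(rng.integers(2, 4)))
            while (sizes >= 2).sum() < 2 or sizes.sum() <= sizes.size:
                sizes = rng.integers(1, 4, size=int(rng.integers(2, 4)))
            fm = random_grouped_matrix(rng, n_features=n, sizes=sizes)
            expected = brute_force_f(fm.values, fm.groups)
            got = f_quantro(fm).f_quantro
            assert got == pytest.approx(expected, rel=1e-10)

    def test_location_invariance_and_scale_equivariance(self):
        rng = np.random.default_rng(12)
        fm = random_grouped_matrix(rng, n_features=40, sizes=np.array([3, 4]))
        base = f_quantro(fm)
        shifted = f_quantro(fm.with_values(fm.values + rng.normal(size=fm.n_samples) * 5))
        assert shifted.f_quantro == pytest.approx(base.f_quantro, rel=1e-9)
        scaled = f_quantro(fm.with_values(fm.values * 2.5))
        assert scaled.f_quantro == pytest.approx(base.f_quantro, rel=1e-9)
        assert scaled.ss_total == pytest.approx(base.ss_total * 2.5**2, rel=1e-9)
        assert scaled.ss_between == pytest.approx(base.ss_between * 2.5**2, rel=1e-9)
        assert scaled.ss_within == pytest.approx(base.ss_within * 2.5**2, rel=1e-9)

    def test_degrees_of_freedom_error(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(DataError):
            QuantroTest(X, groups=["a", "b"])


class TestMedianAnova:
    def test_equal_medians_give_zero(self):
        X = np.array([[0, 0, 0, 0], [1, 1, 1, 1], [5, 5, 5, 5]], float)
        fm = FeatureMatrix(X, groups=np.array(["a", "a", "b", "b"], dtype=object))
        res = median_anova(fm)
        assert res.f_stat == 0.0
        assert res.p_value == 1.0

    def test_two_by_two_example_matches_scipy(self):
        # per-sample medians 1, 2 vs 4, 5: SSB = 9, SSW = 1, F = 9 / 0.5 = 18
        X = np.array([[0, 0, 0, 0], [1, 2, 4, 5], [9, 9, 9, 9]], float)
        fm = FeatureMatrix(X, groups=np.array(["a", "a", "b", "b"], dtype=object))
        res = median_anova(fm)
        ref = stats.f_oneway([1.0, 2.0], [4.0, 5.0])
        assert res.f_stat == pytest.approx(18.0)
        assert res.f_stat == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_two_groups_equal_squared_pooled_t(self):
        rng = np.random.default_rng(13)
        fm = random_grouped_matrix(rng, n_features=21, sizes=np.array([4, 6]))
        med = np.median(fm.values, axis=0)
        t = stats.ttest_ind(med[4:], med[:4], equal_var=True)
        res = median_anova(fm)
        assert res.f_stat == pytest.approx(t.statistic**2, rel=1e-9)

    def test_degenerate_zero_within_variance(self):
        X = np.array([[0, 0, 0, 0], [1, 1, 4, 4], [9, 9, 9, 9]], float)
        fm = FeatureMatrix(X, groups=np.array(["a", "a", "b", "b"], dtype=object))
        res = median_anova(fm)
        assert np.isinf(res.f_stat)
        assert res.p_value == 0.0
        assert res.degenerate


class TestPermutationTest:
    def test_exhaustive_worked_example(self, worked_matrix):
        res = QuantroTest(worked_matrix).fit(exhaustive=True)
        # distinct splits give null F values {18, 2/9, 0}; observed is the
        # strict maximum, attained by 2 of the 6 labelings (itself + swap)
        assert res.perm_p == pytest.approx(1 / 3)
        assert res.n_permutations == 6
        finite = sorted(set(np.round(res.perm_stats, 9)))
        assert finite == pytest.approx([0.0, 2 / 9, 18.0])

    def test_addone_lower_bound_and_range(self):
        rng = np.random.default_rng(14)
        fm = random_grouped_matrix(rng, n_features=30, sizes=np.array([3, 3]))
        for b in (1, 7, 50):
            res = QuantroTest(fm).fit(n_permutations=b, seed=1)
            assert 1 / (b + 1) <= res.perm_p <= 1.0

    def test_seed_reproducibility_across_worker_counts(self):
        rng = np.random.default_rng(15)
        fm = random_grouped_matrix(rng, n_features=60, sizes=np.array([4, 4]))
        r1 = QuantroTest(fm).fit(n_permutations=80, seed=7, n_workers=1)
        r4 = QuantroTest(fm).fit(n_permutations=80, seed=7, n_workers=4)
        assert r1.perm_p == r4.perm_p
        np.testing.assert_array_equal(r1.perm_stats, r4.perm_stats)
        r_other = QuantroTest(fm).fit(n_permutations=80, seed=8)
        assert not np.array_equal(r1.perm_stats, r_other.perm_stats)

    def test_exhaustive_cap_suggests_random_mode(self):
        rng = np.random.default_rng(16)
        fm = random_grouped_matrix(rng, n_features=10, sizes=np.array([6, 6]))
        with pytest.raises(DataError, match="random"):
            QuantroTest(fm).fit(exhaustive=True, max_exhaustive=100)

    def test_requires_two_groups_with_replicates(self):
        X = np.random.default_rng(17).normal(size=(10, 4))
        with pytest.raises(DataError):
            QuantroTest(X, groups=["a", "b", "b", "b"]).fit(n_permutations=10)

    def test_summary_and_dict_roundtrip(self, worked_matrix):
        res = QuantroTest(worked_matrix).fit(exhaustive=True, alpha=0.05)
        text = res.summary()
        assert "F_quantro: 18" in text
        d = res.to_dict(include_perm_stats=True)
        assert d["f_quantro"] == pytest.approx(18.0)
        assert d["global_differences"] is False
        assert len(d["perm_stats"]) == 6
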