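"""Statistics: every operation against independent formula/permutation oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lafib import stats
from scipy import stats as sps


# ---------------------------------------------------------------------------
# textbook-formula oracles (independent of scipy and of the implementation)
# ---------------------------------------------------------------------------

def _rank_avg(x):
    """Average ranks (1-based) with ties."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def friedman_oracle(table):
    """Friedman chi-square with average-rank tie correction, from scratch."""
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    ranks = np.vstack([_rank_avg(row) for row in table])
    rj = ranks.sum(axis=0)
    chisq = 12.0 / (n * k * (k + 1)) * np.sum(rj ** 2) - 3.0 * n * (k + 1)
    # tie correction
    ties = 0.0
    for row in table:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts ** 3 - counts)
    c = 1.0 - ties / (n * k * (k ** 2 - 1))
    if c <= 0:
        return 0.0, 1.0
    chisq /= c
    p = sps.chi2.sf(chisq, k - 1)
    return chisq, p


def kruskal_oracle(groups):
    """Kruskal-Wallis H with tie correction, from scratch."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = _rank_avg(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    c = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    if c > 0:
        h /= c
    return h, sps.chi2.sf(h, len(groups) - 1)


def welch_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    dof = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    p = 2 * sps.t.sf(abs(t), dof)
    return t, p


def chi2_oracle(table):
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expect = rows @ cols / table.sum()
    chisq = np.sum((table - expect) ** 2 / expect)
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    return chisq, sps.chi2.sf(chisq, dof)


# ---------------------------------------------------------------------------
# temporal coefficient of variation
# ---------------------------------------------------------------------------

class TestTemporalCov:
    def test_definition(self):
        series = [8.0, 10.0, 12.0]  # mean 10, sd 2
        assert stats.temporal_cov(series) == pytest.approx(20.0)

    def test_constant_series_zero(self):
        assert stats.temporal_cov([4.0] * 9) == 0.0

    def test_zero_mean_flagged(self):
        assert np.isnan(stats.temporal_cov([0.0] * 9))

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.uniform(1, 50, 9)
            mean = sum(x) / len(x)
            sd = np.sqrt(sum((v - mean) ** 2 for v in x) / (len(x) - 1))
            assert stats.temporal_cov(x) == pytest.approx(100 * sd / mean,
                                                          abs=1e-10)

    @given(st.floats(0.01, 1e3), st.integers(0, 10 ** 6))
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(1, 20, 9)
        assert stats.temporal_cov(c * x) == pytest.approx(
            stats.temporal_cov(x), rel=1e-9)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            stats.temporal_cov([1.0])


# ---------------------------------------------------------------------------
# Friedman
# ---------------------------------------------------------------------------

class TestFriedman:
    def test_identical_columns_degenerate(self):
        table = np.full((9, 10), 3.0)
        assert stats.friedman_consistency(table) == (0.0, 1.0)

    def test_persistently_top_region_significant(self):
        rng = np.random.default_rng(0)
        table = rng.uniform(0, 5, (9, 10))
        table[:, 4] += 50.0  # one region always ranks top
        _, p = stats.friedman_consistency(table)
        assert p < 0.05

    def test_matches_formula_oracle_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            table = rng.uniform(0, 10, (rng.integers(4, 10),
                                        rng.integers(3, 8)))
            got = stats.friedman_consistency(table)
            want = friedman_oracle(table)
            assert got[0] == pytest.approx(want[0], abs=1e-8)
            assert got[1] == pytest.approx(want[1], abs=1e-10)

    def test_rank_test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        table = rng.uniform(0.1, 5, (9, 10))
        a = stats.friedman_consistency(table)
        b = stats.friedman_consistency(np.exp(table))
        assert a[0] == pytest.approx(b[0], abs=1e-9)

    def test_small_table_rejected(self):
        with pytest.raises(ValueError):
            stats.friedman_consistency(np.ones((1, 10)))


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

class TestKruskal:
    def test_two_group_hand_example(self):
        groups = [[1.0, 2.0, 3.0], [10.0, 11.0, 12.0]]
        got = stats.kruskal_regions(groups)
        want = kruskal_oracle([np.array(g) for g in groups])
        assert got[0] == pytest.approx(want[0], abs=1e-10)

    def test_identical_groups_p_one(self):
        assert stats.kruskal_regions([[2.0, 2.0], [2.0, 2.0]]) == (0.0, 1.0)

    def test_matches_formula_oracle_on_random_groups(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            groups = [rng.uniform(0, 10, rng.integers(3, 9))
                      for _ in range(rng.integers(2, 6))]
            got = stats.kruskal_regions(groups)
            want = kruskal_oracle(groups)
            assert got[0] == pytest.approx(want[0], abs=1e-8)

    def test_null_calibration_by_permutation(self):
        """Rejection rate under label permutation stays near alpha."""
        rng = np.random.default_rng(9)
        pooled = rng.normal(0, 1, 30)
        rejections = 0
        n_perm = 400
        for _ in range(n_perm):
            rng.shuffle(pooled)
            _, p = stats.kruskal_regions([pooled[:10], pooled[10:20],
                                          pooled[20:]])
            rejections += p < 0.05
        rate = rejections / n_perm
        assert rate < 0.10  # nominal 0.05 within Monte-Carlo slack

    def test_nan_values_excluded(self):
        got = stats.kruskal_regions([[1.0, np.nan, 2.0], [3.0, 4.0]])
        want = kruskal_oracle([np.array([1.0, 2.0]), np.array([3.0, 4.0])])
        assert got[0] == pytest.approx(want[0], abs=1e-10)


# ---------------------------------------------------------------------------
# grouped Welch t-test
# ---------------------------------------------------------------------------

class TestGroupedTTest:
    def _table(self, rng, shift=0.0):
        arr = rng.uniform(40, 80, (5, 10))
        for r in stats.GROUP_UNSTABLE:
            arr[:, r - 1] += shift
        return pd.DataFrame(arr, columns=[f"R{r}" for r in range(1, 11)])

    def test_identical_groups_boundary(self):
        arr = np.tile(np.arange(10.0), (4, 1)) * 0 + 5.0
        res = stats.grouped_cov_ttest(arr)
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_matches_welch_oracle(self):
        rng = np.random.default_rng(2)
        table = self._table(rng, shift=10.0)
        res = stats.grouped_cov_ttest(table)
        a = table.iloc[:, [r - 1 for r in stats.GROUP_UNSTABLE]].to_numpy().ravel()
        b = table.iloc[:, [r - 1 for r in stats.GROUP_STABLE]].to_numpy().ravel()
        t, p = welch_oracle(a, b)
        assert res["t"] == pytest.approx(t, abs=1e-10)
        assert res["p"] == pytest.approx(p, abs=1e-12)
        assert res["n_a"] == 30 and res["n_b"] == 20

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(4)
        res = stats.grouped_cov_ttest(self._table(rng, shift=30.0))
        assert res["mean_a"] > res["mean_b"]
        assert res["p"] < 0.001


# ---------------------------------------------------------------------------
# chi-square on ablation outcomes
# ---------------------------------------------------------------------------

class TestChiSquare:
    def test_reported_collapsed_outcome_table(self):
        # maintained vs changed-or-terminated at the three ablation extents
        stat, p = stats.chi_square_outcomes([[54, 36], [39, 51], [22, 68]])
        assert p < 0.001

    def test_equal_rows_degenerate(self):
        stat, p = stats.chi_square_outcomes([[10, 5], [10, 5]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_formula(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            table = rng.integers(1, 40, (3, 2))
            got = stats.chi_square_outcomes(table)
            want = chi2_oracle(table)
            assert got[0] == pytest.approx(want[0], abs=1e-8)
            assert got[1] == pytest.approx(want[1], abs=1e-10)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            stats.chi_square_outcomes(np.zeros((0, 2)))
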