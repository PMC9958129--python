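"""Exact rank tests against independent enumeration oracles and scipy/pingouin."""

import itertools

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from nociquant import stats_core as sc


# ---------------------------------------------------------------------------
# brute-force oracles, written over raw values (not ranks) so they share no
# code path with the implementation
# ---------------------------------------------------------------------------

def mwu_oracle(x, y):
    """Enumerate all splits of the pooled values into groups of the observed sizes."""
    pooled = list(x) + list(y)
    nx = len(x)
    idx = range(len(pooled))

    def u_min(ix):
        xs = [pooled[i] for i in ix]
        ys = [pooled[i] for i in idx if i not in ix]
        u_x = sum(
            sum(1.0 if xv > yv else 0.5 if xv == yv else 0.0 for yv in ys) for xv in xs
        )
        return min(u_x, nx * len(ys) - u_x)

    observed = u_min(tuple(range(nx)))
    hits = total = 0
    for combo in itertools.combinations(idx, nx):
        if u_min(combo) <= observed + 1e-9:
            hits += 1
        total += 1
    return observed, min(1.0, hits / total)


def wsr_oracle(diffs):
    """Enumerate all sign flips of the observed |differences|."""
    d = [v for v in diffs if v != 0]
    absd = [abs(v) for v in d]
    ranks = sps.rankdata(absd)

    def w_min(signs):
        w_plus = sum(r for r, s in zip(ranks, signs) if s > 0)
        return min(w_plus, sum(ranks) - w_plus)

    observed = w_min([1 if v > 0 else -1 for v in d])
    n = len(d)
    hits = sum(
        1 for signs in itertools.product((1, -1), repeat=n) if w_min(signs) <= observed + 1e-9
    )
    return observed, min(1.0, hits / 2**n)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_single_pair_two_arrangements(self):
        res = sc.mann_whitney_u([1.0], [2.0])
        assert res.statistic == 0.0
        assert res.p_two_sided == 1.0
        assert res.method == "exact"

    def test_three_vs_three_fully_separated(self):
        res = sc.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_two_sided == pytest.approx(0.1)  # 2/20 arrangements as extreme

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_oracle_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(1, 6), rng.integers(1, 6)
        # half the cases get heavy ties via integer values
        if seed % 2:
            x, y = rng.integers(0, 4, nx).astype(float), rng.integers(0, 4, ny).astype(float)
        else:
            x, y = rng.normal(size=nx), rng.normal(size=ny)
        res = sc.mann_whitney_u(x, y)
        u_ref, p_ref = mwu_oracle(x, y)
        assert res.statistic == pytest.approx(u_ref)
        assert res.p_two_sided == pytest.approx(p_ref)

    def test_matches_scipy_exact_when_no_ties(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=5), rng.normal(size=4)
        res = sc.mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert min(ref.statistic, len(x) * len(y) - ref.statistic) == pytest.approx(res.statistic)
        assert res.p_two_sided == pytest.approx(ref.pvalue)

    @given(st.floats(-50, 50))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_shift_invariance(self, shift):
        x, y = [1.0, 2.5, 4.0], [2.0, 5.0]
        a = sc.mann_whitney_u(x, y)
        b = sc.mann_whitney_u([v + shift for v in x], [v + shift for v in y])
        assert a.statistic == b.statistic and a.p_two_sided == b.p_two_sided

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            sc.mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

class TestWilcoxonSignedRank:
    @pytest.mark.parametrize(
        "n,expected_p", [(5, 2 / 32), (6, 2 / 64)], ids=["n5", "n6"]
    )
    def test_all_one_sign(self, n, expected_p):
        res = sc.wilcoxon_signed_rank(list(range(1, n + 1)))
        assert res.statistic == 0.0
        assert res.p_two_sided == pytest.approx(expected_p)
        assert res.method == "exact"

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = rng.integers(2, 9)
        d = rng.normal(size=n)
        if seed % 2:  # force |d| ties
            d = np.round(d * 2) / 2
            d = d[d != 0]
            if d.size == 0:
                d = np.array([1.0])
        res = sc.wilcoxon_signed_rank(d)
        w_ref, p_ref = wsr_oracle(list(d))
        assert res.statistic == pytest.approx(w_ref)
        assert res.p_two_sided == pytest.approx(p_ref)

    def test_negation_invariance(self):
        d = [0.3, -1.2, 2.2, 0.7, -0.1]
        a = sc.wilcoxon_signed_rank(d)
        b = sc.wilcoxon_signed_rank([-v for v in d])
        assert a.statistic == b.statistic and a.p_two_sided == b.p_two_sided

    def test_zeros_dropped_and_counted(self):
        res = sc.wilcoxon_signed_rank([0.0, 1.0, -2.0, 0.0])
        assert res.n == (2,)
        assert res.extra["n_zeros_dropped"] == 2

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            sc.wilcoxon_signed_rank([0.0, 0.0])


# ---------------------------------------------------------------------------
# Friedman
# ---------------------------------------------------------------------------

class TestFriedman:
    def test_identical_columns_null(self):
        res = sc.friedman_test([[1, 1, 1], [2, 2, 2], [5, 5, 5]])
        assert res.statistic == 0.0
        assert res.p_two_sided == 1.0

    def test_three_blocks_consistently_ordered(self):
        res = sc.friedman_test([[1, 2, 3], [4, 5, 6], [0.1, 0.2, 0.3]])
        assert res.statistic == pytest.approx(6.0)
        assert res.p_two_sided == pytest.approx(6 / 216)
        assert res.method == "exact"

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(size=(4, 3))
        a = sc.friedman_test(mat)
        b = sc.friedman_test(np.exp(mat))  # strictly increasing transform
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_two_sided == pytest.approx(b.p_two_sided)

    def test_statistic_matches_scipy_on_larger_design(self):
        rng = np.random.default_rng(8)
        mat = rng.normal(size=(12, 4))
        res = sc.friedman_test(mat)
        ref = sps.friedmanchisquare(*mat.T)
        assert res.method == "chi-square"
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_two_sided == pytest.approx(ref.pvalue)

    def test_degenerate_shapes_rejected(self):
        with pytest.raises(ValueError):
            sc.friedman_test([[1, 2, 3]])


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Welch's ANOVA
# ---------------------------------------------------------------------------

class TestKruskalWallis:
    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(size=6), rng.normal(1.0, 2.0, size=5), rng.normal(size=4)]
        res = sc.kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_two_sided == pytest.approx(ref.pvalue)

    def test_handles_ties_like_scipy(self):
        groups = [[1, 1, 2], [2, 3, 3], [1, 3, 4]]
        res = sc.kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic)


class TestWelchAnova:
    def test_identical_groups_null(self):
        g = [1.0, 2.0, 3.0]
        res = sc.welch_anova([g, list(g), list(g)])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_two_groups_equal_squared_welch_t(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=7), rng.normal(0.5, 3.0, size=5)
        res = sc.welch_anova([x, y])
        t = sps.ttest_ind(x, y, equal_var=False)
        assert res.statistic == pytest.approx(t.statistic**2)
        assert res.p_two_sided == pytest.approx(t.pvalue)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(6)
        groups = [rng.normal(size=8), rng.normal(1, 2, size=6), rng.normal(-1, 0.5, size=7)]
        res = sc.welch_anova(groups)
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat(np.arange(3), [len(g) for g in groups]),
            }
        )
        ref = pg.welch_anova(data=df, dv="y", between="g")
        assert res.statistic == pytest.approx(float(ref["F"].iloc[0]))
        assert res.p_two_sided == pytest.approx(float(ref["p_unc"].iloc[0]))
        assert res.extra["df2"] == pytest.approx(float(ref["ddof2"].iloc[0]))

    def test_type_one_error_calibration_under_null(self):
        # unequal variances, 3 groups, size-alpha behavior of the F reference
        rng = np.random.default_rng(99)
        n_reps, alpha = 4000, 0.05
        rejections = 0
        for _ in range(n_reps):
            groups = [
                rng.normal(0, 1, size=8),
                rng.normal(0, 3, size=6),
                rng.normal(0, 0.5, size=10),
            ]
            if sc.welch_anova(groups).p_two_sided < alpha:
                rejections += 1
        rate = rejections / n_reps
        assert abs(rate - alpha) < 0.012  # ~3.5 MC SD

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            sc.welch_anova([[1.0, 1.0], [2.0, 3.0]])


def test_permutation_invariance_within_groups():
    rng = np.random.default_rng(11)
    x, y = rng.normal(size=6), rng.normal(size=5)
    a = sc.mann_whitney_u(x, y)
    b = sc.mann_whitney_u(x[::-1], rng.permutation(y))
    assert a.statistic == b.statistic and a.p_two_sided == b.p_two_sided
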