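"""Nonparametric rank tests with exact small-sample null distributions.

Every test returns a :class:`TestResult`.  For small designs the null
distribution is enumerated in full (group-label arrangements for the rank-sum
test, sign patterns for the signed-rank test, within-block permutations for
the Friedman test), so the p-values are exact even under ties, which are
handled with midranks throughout.  Larger designs fall back to the standard
large-sample approximations with tie corrections.

Two-sided p-values are obtained by doubling the smaller one-sided tail and
capping at 1 — the convention most software applies to discrete nulls.
Zeros among signed-rank differences are dropped before ranking.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "friedman_test",
    "kruskal_wallis",
    "welch_anova",
]

#: largest number of null arrangements enumerated exactly
EXACT_ENUMERATION_LIMIT = 1_000_000


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_two_sided: float
    n: tuple[int, ...]
    method: str  # "exact" | "normal-approximation" | "chi-square" | "f-distribution"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_two_sided <= 1.0):
            raise AssertionError(f"p-value out of (0, 1]: {self.p_two_sided}")


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


# ---------------------------------------------------------------------------
# Mann–Whitney U (unpaired Wilcoxon rank-sum)
# ---------------------------------------------------------------------------

def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann–Whitney U test.

    The reported statistic is the smaller of the two U orientations (both are
    kept in ``extra``).  When the number of group-label arrangements
    C(nx+ny, nx) is at most :data:`EXACT_ENUMERATION_LIMIT` the p-value is
    exact: all arrangements of the observed (mid)ranks are enumerated, so ties
    are handled exactly as observed.  Otherwise the normal approximation with
    tie correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    ranks = _midranks(np.concatenate([x, y]))
    u_x = float(ranks[:nx].sum()) - nx * (nx + 1) / 2.0
    u_y = nx * ny - u_x
    u = min(u_x, u_y)

    if math.comb(nx + ny, nx) <= EXACT_ENUMERATION_LIMIT:
        p = _mwu_exact_p(ranks, nx, u)
        method = "exact"
    else:
        # normal approximation with tie correction
        n = nx + ny
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts))
        sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        mu = nx * ny / 2.0
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (u - mu + 0.5) / math.sqrt(sigma2)  # continuity corrected
            p = min(1.0, 2.0 * sps.norm.cdf(z))
        method = "normal-approximation"
    return TestResult(
        name="mann-whitney-u",
        statistic=u,
        p_two_sided=max(p, np.finfo(float).tiny),
        n=(nx, ny),
        method=method,
        extra={"u_x": u_x, "u_y": u_y},
    )


def _mwu_exact_p(ranks: np.ndarray, nx: int, u_obs: float) -> float:
    """P(min(U) <= u_obs) doubled, by enumeration of rank-label arrangements."""
    n = ranks.size
    ny = n - nx
    offset = nx * (nx + 1) / 2.0
    hits = 0
    total = 0
    tol = 1e-9
    for combo in itertools.combinations(range(n), nx):
        u_x = ranks[list(combo)].sum() - offset
        u_min = min(u_x, nx * ny - u_x)
        if u_min <= u_obs + tol:
            hits += 1
        total += 1
    return min(1.0, hits / total)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(differences) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped.  W is the smaller of the positive- and
    negative-rank sums.  For n <= 20 retained pairs the 2**n sign patterns of
    the observed |difference| midranks are enumerated, giving an exact
    p-value; larger n uses the normal approximation with tie correction.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    n = d.size
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    if 2**n <= EXACT_ENUMERATION_LIMIT:
        p = _wsr_exact_p(ranks, w)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts))
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
        z = (w - mu + 0.5) / math.sqrt(sigma2)
        p = min(1.0, 2.0 * sps.norm.cdf(z))
        method = "normal-approximation"
    return TestResult(
        name="wilcoxon-signed-rank",
        statistic=w,
        p_two_sided=max(p, np.finfo(float).tiny),
        n=(n,),
        method=method,
        extra={"w_plus": w_plus, "w_minus": w_minus, "n_zeros_dropped": int(np.sum(np.asarray(differences) == 0))},
    )


def _wsr_exact_p(ranks: np.ndarray, w_obs: float) -> float:
    """P(min(W+, W-) <= w_obs) doubled (equivalently counted directly)."""
    n = ranks.size
    total_rank_sum = float(ranks.sum())
    hits = 0
    tol = 1e-9
    for signs in itertools.product((0, 1), repeat=n):
        w_plus = float(sum(r for r, s in zip(ranks, signs) if s))
        w_min = min(w_plus, total_rank_sum - w_plus)
        if w_min <= w_obs + tol:
            hits += 1
    return min(1.0, hits / 2**n)


# ---------------------------------------------------------------------------
# Friedman test
# ---------------------------------------------------------------------------

def _friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from a blocks x treatments rank matrix."""
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    ss = float(np.sum((col_sums - n * (k + 1) / 2.0) ** 2))
    # tie correction: for each block, sum over tie groups of (t^3 - t)
    correction = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        correction += float(np.sum(counts**3 - counts))
    chi2 = 12.0 * ss / (n * k * (k + 1))
    c = 1.0 - correction / (n * k * (k * k - 1))
    if c <= 0:
        return 0.0  # all values tied within every block
    return chi2 / c


def friedman_test(data) -> TestResult:
    """Friedman test on a blocks x treatments matrix.

    Within-block midranks; tie-corrected chi-square statistic.  For designs
    with (k!)**n <= :data:`EXACT_ENUMERATION_LIMIT` the p-value is exact by
    enumerating independent within-block permutations; otherwise the
    chi-square distribution with k-1 degrees of freedom is used.
    """
    mat = np.asarray(data, dtype=float)
    if mat.ndim != 2:
        raise ValueError("data must be a 2-D blocks x treatments matrix")
    n, k = mat.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 blocks and >= 2 treatments")
    ranks = np.apply_along_axis(_midranks, 1, mat)
    stat = _friedman_statistic(ranks)

    if math.factorial(k) ** n <= EXACT_ENUMERATION_LIMIT:
        perms = list(itertools.permutations(range(k)))
        hits = 0
        total = 0
        tol = 1e-9
        for assignment in itertools.product(perms, repeat=n):
            permuted = np.vstack([ranks[i, list(p)] for i, p in enumerate(assignment)])
            if _friedman_statistic(permuted) >= stat - tol:
                hits += 1
            total += 1
        p = hits / total
        method = "exact"
    else:
        p = float(sps.chi2.sf(stat, df=k - 1))
        method = "chi-square"
    return TestResult(
        name="friedman",
        statistic=stat,
        p_two_sided=max(min(p, 1.0), np.finfo(float).tiny),
        n=(n, k),
        method=method,
    )


# ---------------------------------------------------------------------------
# Kruskal–Wallis
# ---------------------------------------------------------------------------

def kruskal_wallis(groups) -> TestResult:
    """Kruskal–Wallis H test on a list of samples (midranks, tie-corrected).

    p from the chi-square distribution with (g-1) degrees of freedom.
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2 or any(s.size == 0 for s in samples):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(samples)
    n = pooled.size
    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for s in samples:
        r = ranks[start : start + s.size]
        h += r.sum() ** 2 / s.size
        start += s.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(ranks, return_counts=True)
    c = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    if c > 0:
        h /= c
    p = float(sps.chi2.sf(h, df=len(samples) - 1))
    return TestResult(
        name="kruskal-wallis",
        statistic=float(h),
        p_two_sided=max(min(p, 1.0), np.finfo(float).tiny),
        n=tuple(s.size for s in samples),
        method="chi-square",
    )


# ---------------------------------------------------------------------------
# Welch's ANOVA
# ---------------------------------------------------------------------------

def welch_anova(groups) -> TestResult:
    """Welch's heteroscedastic one-way ANOVA.

    W statistic with p from the F distribution at (g-1, Welch–Satterthwaite)
    degrees of freedom.  With two groups W equals the squared Welch t
    statistic.
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    g = len(samples)
    if g < 2:
        raise ValueError("need >= 2 groups")
    for s in samples:
        if s.size < 2:
            raise ValueError("every group needs >= 2 values")
        if np.var(s, ddof=1) == 0:
            raise ValueError("zero within-group variance")
    ns = np.array([s.size for s in samples], dtype=float)
    means = np.array([s.mean() for s in samples])
    variances = np.array([np.var(s, ddof=1) for s in samples])
    weights = ns / variances
    w_sum = weights.sum()
    grand = float(np.sum(weights * means) / w_sum)
    numerator = float(np.sum(weights * (means - grand) ** 2) / (g - 1))
    lam = float(np.sum((1 - weights / w_sum) ** 2 / (ns - 1)))
    denominator = 1.0 + 2.0 * (g - 2) / (g * g - 1.0) * lam
    w_stat = numerator / denominator
    df2 = (g * g - 1.0) / (3.0 * lam) if lam > 0 else np.inf
    p = float(sps.f.sf(w_stat, g - 1, df2))
    return TestResult(
        name="welch-anova",
        statistic=w_stat,
        p_two_sided=max(min(p, 1.0), np.finfo(float).tiny),
        n=tuple(int(v) for v in ns),
        method="f-distribution",
        extra={"df1": g - 1, "df2": df2},
    )
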