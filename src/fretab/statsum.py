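"""Nonparametric comparisons and figure-style summaries for condition tables.

The central test is the Wilcoxon signed-rank test with an *exact* two-sided
p-value obtained from the full null distribution of the positive-rank sum
(all 2^n sign assignments) for n ≤ 25, and a normal approximation with tie
and continuity corrections beyond that.  Significance stars follow the
banding * p ≤ 0.05, ** p ≤ 0.009, *** p ≤ 0.0009.  Boxplot summaries use the
Tukey convention (whiskers to the furthest observation within 1.5·IQR of the
quartiles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "BoxplotSummary",
    "wilcoxon_signed_rank",
    "rank_sum",
    "compare_groups",
    "star_annotation",
    "boxplot_summary",
    "EXACT_MAX_N",
]

#: Largest sample size (nonzero differences) for which the exact null
#: distribution of the signed-rank statistic is enumerated.
EXACT_MAX_N = 25

_STAR_BANDS = ((0.0009, "***"), (0.009, "**"), (0.05, "*"))


@dataclass(frozen=True)
class StatResult:
    """Outcome of one pairwise comparison."""

    pair: tuple[str, str]
    test: str
    statistic: float
    p_value: float
    stars: str
    n: tuple[int, int]
    method: str
    n_zero_dropped: int = 0


@dataclass(frozen=True)
class BoxplotSummary:
    """Tukey five-number summary with explicit outliers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]
    n: int


def star_annotation(p: float) -> str:
    """Map a p-value to its significance stars ('ns' when p > 0.05)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    for bound, stars in _STAR_BANDS:
        if p <= bound:
            return stars
    return "ns"


def _exact_signed_rank_pmf(ranks2: np.ndarray) -> np.ndarray:
    """Null pmf of the doubled positive-rank sum via polynomial convolution.

    ``ranks2`` holds the ranks of |differences| multiplied by two so midranks
    (ties) become integers.  Entry k of the result is the probability that the
    doubled positive-rank sum equals k under random independent signs; the
    convolution enumerates exactly the 2^n sign assignments.
    """
    total = int(ranks2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf


def wilcoxon_signed_rank(x, y=None, exact_max_n: int = EXACT_MAX_N) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    With ``y`` given, tests the differences ``x - y``; with ``y`` omitted,
    ``x`` itself is taken as the differences.  Zero differences are dropped
    (Wilcoxon's convention) and counted in the result.  The statistic is W+,
    the sum of ranks of positive differences (midranks for ties).  For up to
    ``exact_max_n`` nonzero differences the p-value is exact, from the full
    sign-assignment distribution; otherwise a normal approximation with tie
    and continuity corrections is used, and the method is recorded.
    """
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        d = x - y
    else:
        d = x
    if d.size == 0:
        raise ValueError("no observations")
    n_zero = int((d == 0).sum())
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; the test is undefined")

    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        ranks2 = np.rint(2 * ranks).astype(int)
        pmf = _exact_signed_rank_pmf(ranks2)
        w2 = int(round(2 * w_plus))
        cdf_le = pmf[: w2 + 1].sum()
        cdf_ge = pmf[w2:].sum()
        p = min(1.0, 2.0 * min(cdf_le, cdf_ge))
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = (counts**3 - counts).sum() / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        # continuity correction toward the mean
        z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sigma
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        method = "normal-approx"

    return StatResult(
        pair=("x", "y"),
        test="wilcoxon-signed-rank",
        statistic=w_plus,
        p_value=float(p),
        stars=star_annotation(float(p)),
        n=(n, n),
        method=method,
        n_zero_dropped=n_zero,
    )


def rank_sum(x, y) -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test for unpaired groups."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    p = float(res.pvalue)
    return StatResult(
        pair=("x", "y"),
        test="rank-sum",
        statistic=float(res.statistic),
        p_value=p,
        stars=star_annotation(p),
        n=(x.size, y.size),
        method="mann-whitney",
    )


def compare_groups(x, y, labels=("a", "b"), test: str = "signed-rank") -> StatResult:
    """Compare two condition groups of per-cell efficiencies.

    ``signed-rank`` applies the paired test; when the groups are independent
    but of equal size they are paired by rank order within each group, the
    convention used when a paired test is applied to matched experiment
    batches.  Unequal group sizes fall back to the rank-sum test (recorded in
    ``method``).  ``rank-sum`` forces the unpaired test, the statistically
    safer choice for independent cell populations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if test == "rank-sum":
        res = rank_sum(x, y)
        return StatResult(**{**res.__dict__, "pair": tuple(labels)})
    if test != "signed-rank":
        raise ValueError(f"unknown test {test!r}")
    if x.size == y.size and x.size > 0:
        res = wilcoxon_signed_rank(np.sort(x), np.sort(y))
        method = f"{res.method}, rank-order pairing"
        return StatResult(**{**res.__dict__, "pair": tuple(labels), "method": method})
    res = rank_sum(x, y)
    return StatResult(
        **{**res.__dict__, "pair": tuple(labels), "method": "rank-sum fallback (unequal n)"}
    )


def boxplot_summary(values) -> BoxplotSummary:
    """Tukey boxplot summary with linear-interpolation quartiles."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = tuple(float(o) for o in np.sort(v[(v < lo_fence) | (v > hi_fence)]))
    return BoxplotSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
        n=int(v.size),
    )
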