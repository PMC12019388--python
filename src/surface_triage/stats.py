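"""Shared rank-based test statistics.

Implements the two primitives every differential-expression stage of the
pipeline relies on: the two-sample Wilcoxon rank-sum (Mann-Whitney) test and
Benjamini-Hochberg step-up FDR adjustment.  Both are written from their
definitions so that tests can hold them against independent oracles
(full permutation enumeration, the explicit step-up formula) at tight
tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["RankTestResult", "wilcoxon_rank_sum", "bh_adjust"]

#: largest combined sample size for which the exact null distribution is used
DEFAULT_EXACT_CUTOFF = 16


@dataclass(frozen=True)
class RankTestResult:
    """Outcome of a two-sample Wilcoxon rank-sum test.

    ``statistic`` is the Mann-Whitney U of the first sample, ``method`` is
    ``"exact"`` or ``"normal-approximation"``.
    """

    statistic: float
    p_value: float
    method: str


def _exact_rank_sum_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of the rank-sum of a size-``n1`` subset of ranks
    ``1..n1+n2`` as an array of counts indexed by rank-sum.

    Classic dynamic program over items; total mass is C(n1+n2, n1).
    """
    n = n1 + n2
    max_sum = sum(range(n - n1 + 1, n + 1))
    # counts[k, s] = number of k-subsets of the ranks seen so far with sum s
    counts = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for rank in range(1, n + 1):
        for k in range(min(rank, n1), 0, -1):
            counts[k, rank:] += counts[k - 1, : max_sum + 1 - rank]
    return counts[n1]


def wilcoxon_rank_sum(
    x,
    y,
    exact_cutoff: int = DEFAULT_EXACT_CUTOFF,
    method: str | None = None,
) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum test of ``x`` versus ``y``.

    Midranks are used for ties.  The exact null distribution (by
    enumeration over rank subsets) is used when ``len(x) + len(y) <=
    exact_cutoff`` and there are no ties, unless ``method`` ("exact" or
    "normal") overrides the choice.  Otherwise a normal approximation with
    tie correction and continuity correction is used.  The two-sided
    p-value is ``min(1, 2 * one-sided)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    if (tie_counts == n1 + n2).any():
        # every value identical: no evidence either way
        return RankTestResult(u1, 1.0, "degenerate")

    if method not in (None, "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    use_exact = (
        method == "exact"
        or (method is None and n1 + n2 <= exact_cutoff and not has_ties)
    )
    if use_exact and has_ties:
        raise ValueError("exact method is undefined with tied values")

    if use_exact:
        counts = _exact_rank_sum_counts(n1, n2)
        total = counts.sum()
        sums = np.arange(counts.size)
        # r1 is integral in the no-ties case
        r1_int = int(round(r1))
        lower = counts[sums <= r1_int].sum() / total
        upper = counts[sums >= r1_int].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        return RankTestResult(u1, p, "exact")

    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return RankTestResult(u1, 1.0, "degenerate")
    sd = np.sqrt(var)
    if u1 > mu:
        one_sided = norm.sf((u1 - mu - 0.5) / sd)
    else:
        one_sided = norm.cdf((u1 - mu + 0.5) / sd)
    p = min(1.0, 2.0 * one_sided)
    return RankTestResult(u1, p, "normal-approximation")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the ascending order
    statistics, capped at 1.  Ties share the adjusted value of their
    common raw p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adjusted = np.empty(m, dtype=float)
    adjusted[order] = adjusted_sorted
    return adjusted
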