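"""Statistical primitives used across the pipeline.

These are deliberately small and self-contained so tests can compare them
against brute-force enumerations.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "bh_fdr",
    "mann_whitney_u",
    "pooled_ttest_from_stats",
    "chi2_2x2",
    "fisher_exact_2x2",
    "contingency_chi2",
]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    q_(i) = min_{j >= i} min(1, p_(j) * n / j) on the sorted p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n, dtype=float)
    q[order] = q_sorted
    return q


@lru_cache(maxsize=None)
def _u_counts(n: int, m: int) -> tuple[int, ...]:
    """Number of arrangements of an n-vs-m comparison achieving each U value
    (no ties), via the standard recursion; index u in [0, n*m]."""
    if n == 0 or m == 0:
        return (1,)
    a = _u_counts(n - 1, m)  # last rank goes to group 1: adds m to U? no: adds 0
    b = _u_counts(n, m - 1)
    # If the largest observation is from group x (size n), it beats all m ys:
    # U increases by m.  If from group y, U unchanged.
    out = [0] * (n * m + 1)
    for u, c in enumerate(a):
        out[u + m] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution (via the counting recursion) when there are no
    ties and both groups have <= 8 observations; otherwise a normal
    approximation with mid-rank tie correction and continuity correction.
    Returns (U of the first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[:n].sum() - n * (n + 1) / 2)
    u2 = n * m - u1
    has_ties = len(np.unique(pooled)) < n + m
    if not has_ties and max(n, m) <= 8:
        counts = _u_counts(n, m)
        total = sum(counts)
        u_min = min(u1, u2)
        tail = sum(counts[: int(u_min) + 1])
        p = min(1.0, 2.0 * tail / total)
        return u1, p
    # normal approximation
    mu = n * m / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    nn = n + m
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (nn * (nn - 1))
    sigma2 = n * m / 12.0 * ((nn + 1) - tie_term)
    if sigma2 <= 0:
        return u1, 1.0
    z = (abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(sps.norm.sf(z)))
    return u1, p


def pooled_ttest_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Two-tailed pooled-variance two-sample t-test from summary statistics.

    df = n1 + n2 - 2.  Returns (t, p).  Degenerate inputs (zero pooled
    variance) give t = 0, p = 1 when the means are equal.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("need n >= 2 in both groups")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        if mean1 == mean2:
            return 0.0, 1.0
        return float("inf"), 0.0
    t = (mean1 - mean2) / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), min(1.0, p)


def chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-squared (no Yates correction) on a 2x2 table; (stat, p)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError("expected a 2x2 table")
    if t.sum() == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 0.0, 1.0
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValidationError("expected a 2x2 table")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def contingency_chi2(table) -> tuple[float, float]:
    """Pearson chi-squared (no correction) on an r x c contingency table.

    Rows/columns with zero totals are dropped before testing; a table with
    fewer than 2 informative rows or columns yields (0, 1).
    """
    t = np.asarray(table, dtype=float)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 0.0, 1.0
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p)
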