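"""Rank and significance statistics for benchmarking predictions.

Implemented from their definitions so the package is self-verifying
against enumeration oracles: ROC/AUC with the Mann-Whitney half-credit
tie convention, the paired Wilcoxon signed-rank test (exact null
distribution for small samples), one-sided t-tests (paired and Welch),
and Benjamini-Hochberg FDR adjustment.  Only distribution CDFs are
delegated to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ROCResult",
    "TestResult",
    "roc_auc",
    "wilcoxon_signed_rank",
    "t_test_one_sided",
    "bh_adjust",
]

#: exact Wilcoxon enumeration up to this many non-zero differences
_WILCOXON_EXACT_N = 25


@dataclass(frozen=True)
class ROCResult:
    """AUC with the underlying ROC curve.

    ``auc`` equals the Mann-Whitney U statistic over n_pos * n_neg:
    ties between a positive and a negative score earn half credit.
    """

    auc: float
    n_pos: int
    n_neg: int
    curve_points: tuple


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    method: str
    flag: Optional[str] = None


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> ROCResult:
    """ROC curve and AUC of ``scores`` against binary ``labels``.

    Higher scores should indicate the positive class.  The curve is
    built by descending-score thresholding with tied scores grouped
    into a single step, so it starts at (0, 0) and ends at (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0:
        raise ValueError("no positive labels")
    if n_neg == 0:
        raise ValueError("no negative labels")
    # Mann-Whitney via midranks: half credit for pos/neg ties
    ranks = _sps.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = np.argsort(-scores, kind="mergesort")
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            tp += int(labels[order[j]])
            fp += int(~labels[order[j]])
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    return ROCResult(auc=float(auc), n_pos=n_pos, n_neg=n_neg,
                     curve_points=tuple(points))


def _signed_rank_null_tail(doubled_ranks: np.ndarray, w2: int, tail: str) -> float:
    """P(W+*2 >= w2) or <= under random independent signs, by subset-sum DP.

    Equivalent to enumerating all 2^n sign patterns; doubled midranks
    keep the sums integral in the presence of ties.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    if tail == "ge":
        return float(counts[w2:].sum())
    return float(counts[: w2 + 1].sum())


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> TestResult:
    """Paired Wilcoxon signed-rank test.

    Zero differences are dropped.  For up to 25 non-zero differences
    the p-value is exact over the null distribution of all sign
    patterns (midranks for ties); beyond that a normal approximation
    with tie correction and continuity correction is used.  The
    statistic is W+, the rank sum of positive differences.
    ``alternative='greater'`` tests a positive shift of x over y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult(statistic=0.0, pvalue=1.0, method="wilcoxon",
                          flag="all differences zero")
    ranks = _sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= _WILCOXON_EXACT_N:
        doubled = np.rint(2 * ranks).astype(int)
        w2 = int(round(2 * w_plus))
        p_ge = _signed_rank_null_tail(doubled, w2, "ge")
        p_le = _signed_rank_null_tail(doubled, w2, "le")
        method = "wilcoxon-exact"
    else:
        mean = n * (n + 1) / 4
        _uniq, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float((tie_counts**3 - tie_counts).sum()) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        sd = np.sqrt(var)
        p_ge = float(_sps.norm.sf((w_plus - 0.5 - mean) / sd))
        p_le = float(_sps.norm.cdf((w_plus + 0.5 - mean) / sd))
        method = "wilcoxon-normal"
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2 * min(p_ge, p_le))
    return TestResult(statistic=w_plus, pvalue=float(p), method=method)


def t_test_one_sided(
    x: Sequence[float],
    y: Sequence[float],
    paired: bool = False,
    alternative: str = "greater",
) -> TestResult:
    """One-sided t-test of x against y (paired, or Welch two-sample).

    ``alternative='greater'`` tests mean(x) > mean(y).  A degenerate
    zero-variance comparison with equal means returns p = 0.5 with a
    flag (the statistic is 0/0; symmetry of the null motivates 0.5).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        d = x - y
        n = len(d)
        if n < 2:
            raise ValueError("need at least two pairs")
        sd = d.std(ddof=1)
        if sd == 0:
            if d.mean() == 0:
                return TestResult(0.0, 0.5, "t-paired", flag="zero variance")
            t = np.inf * np.sign(d.mean())
        else:
            t = d.mean() / (sd / np.sqrt(n))
        df = n - 1
        method = "t-paired"
    else:
        if len(x) < 2 or len(y) < 2:
            raise ValueError("need at least two observations per sample")
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        nx, ny = len(x), len(y)
        se2 = vx / nx + vy / ny
        if se2 == 0:
            if x.mean() == y.mean():
                return TestResult(0.0, 0.5, "t-welch", flag="zero variance")
            t = np.inf * np.sign(x.mean() - y.mean())
            df = nx + ny - 2
        else:
            t = (x.mean() - y.mean()) / np.sqrt(se2)
            df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        method = "t-welch"
    if alternative == "greater":
        p = float(_sps.t.sf(t, df))
    else:
        p = float(_sps.t.cdf(t, df))
    return TestResult(statistic=float(t), pvalue=p, method=method)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, reported in input order.

    adj_(i) = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj_sorted
    return out.tolist()
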