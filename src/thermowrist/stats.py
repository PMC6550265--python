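"""Nonparametric statistical primitives.

The conventions here are fixed by the analysis contract and therefore
implemented directly rather than delegated: the paired signed-rank test
drops zero differences, uses mid-ranks for tied magnitudes, enumerates all
2**n sign assignments exactly for small n and falls back to a normal
approximation with continuity and tie corrections otherwise; the MAD is
unscaled (no normal-consistency constant); AUROC is the Mann-Whitney
probability with ties counted one half.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm, rankdata

#: Largest number of non-zero differences for which the signed-rank null
#: distribution is enumerated exactly.
EXACT_N_MAX = 12


def median_abs_deviation(x) -> float:
    """Unscaled MAD: median of absolute deviations from the median."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))))


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test of ``y - x``.

    Returns ``(W_plus, p_two_sided)`` where ``W_plus`` is the sum of ranks
    of positive differences. Zero differences are dropped; tied magnitudes
    get mid-ranks. For ``n <= 12`` non-zero differences the p-value is
    exact by full sign enumeration; otherwise a normal approximation with
    continuity correction and tie correction is used.

    Raises
    ------
    ValueError
        If the inputs differ in length, are empty, or all differences are
        zero (the test carries no information).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size == 0:
        raise ValueError("empty input")
    d = y - x
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_N_MAX:
        # all 2**n sign assignments: row b assigns + to the set bits of b
        signs = (
            np.arange(2**n)[:, None] >> np.arange(n)[None, :]
        ) & 1  # (2**n, n) in {0,1}
        w_all = signs @ ranks
        eps = 1e-9
        p_le = np.count_nonzero(w_all <= w_plus + eps) / 2.0**n
        p_ge = np.count_nonzero(w_all >= w_plus - eps) / 2.0**n
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return w_plus, p

    mu = n * (n + 1) / 4.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    sigma2 -= np.sum(counts**3 - counts) / 48.0
    sigma = np.sqrt(sigma2)
    z = (abs(w_plus - mu) - 0.5) / sigma
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return w_plus, p


def effect_size(no_thermal, with_thermal) -> float:
    """Robust paired effect size: median(diff) / MAD(diff), unscaled MAD.

    ``diff = with_thermal - no_thermal``, so a positive value means the
    thermal channels increase the measure.
    """
    a = np.asarray(no_thermal, dtype=float)
    b = np.asarray(with_thermal, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1-d arrays with >= 2 pairs")
    d = b - a
    mad = median_abs_deviation(d)
    if mad == 0.0:
        raise ValueError("MAD of paired differences is zero (degenerate)")
    return float(np.median(d)) / mad


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value, ``min(1, m * p)``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, m * p)


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    Equals the probability that a uniformly random positive example
    receives a higher score than a uniformly random negative one, with
    score ties counted one half. Both classes must be present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d arrays of equal length")
    pos = y == 1
    n_pos = int(pos.sum())
    n_neg = s.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def confusion_matrix(scores, labels, threshold: float = 0.5) -> np.ndarray:
    """2x2 confusion counts at a fixed score threshold.

    Rows are the true class (0 then 1), columns the predicted class, i.e.
    ``[[TN, FP], [FN, TP]]``. Predictions are ``score >= threshold``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d arrays of equal length")
    pred = (s >= threshold).astype(int)
    out = np.zeros((2, 2), dtype=int)
    for t, p in ((0, 0), (0, 1), (1, 0), (1, 1)):
        out[t, p] = int(np.count_nonzero((y == t) & (pred == p)))
    return out
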