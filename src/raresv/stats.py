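"""Effect-size and multiplicity statistics used by the burden comparison.

``cliffs_delta`` and ``holm_sidak`` implement their textbook definitions
exactly (both are contract-tested against brute-force/closed-form oracles);
the two-proportion z test delegates to statsmodels.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.proportion import proportions_ztest

__all__ = ["cliffs_delta", "holm_sidak", "two_proportion_test"]


def cliffs_delta(x, y) -> float:
    """Cliff's delta effect size in [-1, 1].

    delta = (#{x_i > y_j} - #{x_i < y_j}) / (|x| * |y|): the normalized
    excess of greater-than over less-than pairs. Positive values mean x
    tends to exceed y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ys = np.sort(y)
    gt = np.searchsorted(ys, x, side="left").sum()       # y strictly below x_i
    lt = (ys.size - np.searchsorted(ys, x, side="right")).sum()
    return float((int(gt) - int(lt)) / (x.size * y.size))


def holm_sidak(pvals, alpha: float = 0.05):
    """Holm–Šídák step-down adjusted p-values and rejection flags.

    Sorting the raw p-values ascending, the k-th adjusted value is the
    running maximum of ``1 - (1 - p_(j))**(m - j + 1)`` over j <= k, clipped
    at 1, returned in the input order; reject where adjusted <= alpha.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("all p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    expo = m - np.arange(m)
    stepdown = 1.0 - (1.0 - p[order]) ** expo
    stepdown[expo == 1] = p[order][expo == 1]  # exact where the power is 1
    adj_sorted = np.minimum(np.maximum.accumulate(stepdown), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted <= alpha


def two_proportion_test(count1: int, nobs1: int, count2: int, nobs2: int) -> float:
    """Two-sided pooled two-proportion z test; degenerate inputs give p = 1."""
    if nobs1 <= 0 or nobs2 <= 0:
        return 1.0
    if count1 == count2 == 0 or (count1 == nobs1 and count2 == nobs2):
        return 1.0
    pooled = (count1 + count2) / (nobs1 + nobs2)
    if pooled in (0.0, 1.0):
        return 1.0
    _, p = proportions_ztest([count1, count2], [nobs1, nobs2])
    return float(p) if np.isfinite(p) else 1.0
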