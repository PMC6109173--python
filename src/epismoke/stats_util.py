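"""Small shared statistics: BH step-up FDR and the pooled two-sample t."""
from __future__ import annotations

import numpy as np
from scipy import stats


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def pooled_t(x, y) -> tuple[float, float, int]:
    """Pooled-variance two-sample t of x vs y: (t, two-sided p, df).

    Sign convention: t > 0 iff mean(x) > mean(y).  The degenerate case of
    zero pooled variance returns t=0, p=1 when the means are equal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 observations")
    df = x.size + y.size - 2
    ss = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
    s2 = ss / df
    diff = x.mean() - y.mean()
    if s2 == 0:
        if diff == 0:
            return 0.0, 1.0, df
        return float(np.sign(diff)) * float("inf"), 0.0, df
    t = diff / np.sqrt(s2 * (1 / x.size + 1 / y.size))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0)), df


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch two-sample t of x vs y: (t, two-sided p, df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 observations")
    res = stats.ttest_ind(x, y, equal_var=False)
    if np.isnan(res.statistic):
        return 0.0, 1.0, float(x.size + y.size - 2)
    return float(res.statistic), float(res.pvalue), float(res.df)
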