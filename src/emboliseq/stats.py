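"""Shared statistical utilities."""

from __future__ import annotations

import numpy as np


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    NaN entries are excluded from the number of tests ``m`` and propagate
    as NaN in the output.  Adjusted values are monotone in p-rank and never
    smaller than the raw p.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # step-up: running minimum from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[valid] = res
    return out


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation (t with n-2 df)."""
    from scipy import stats

    if n < 3:
        return float("nan")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))
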