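"""Thin paired-comparison reporting utility.

Normality of the paired differences is screened with the Jarque-Bera test;
normal differences go to the paired t-test, non-normal ones to the Wilcoxon
signed-rank test.  Significance is called at alpha = 0.05 with Bonferroni
correction when several comparisons are made.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["paired_compare"]


def paired_compare(x, y, alpha: float = 0.05,
                   n_comparisons: int = 1) -> dict:
    """Compare paired samples x vs y; returns test choice and p-values."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1D samples with n >= 3")
    d = x - y
    if np.allclose(d, 0.0):
        return {"test": "degenerate", "statistic": 0.0, "p_raw": 1.0,
                "p_adj": 1.0, "normal": True, "significant": False,
                "mean_diff": 0.0}
    jb_stat, jb_p = stats.jarque_bera(d)
    normal = bool(jb_p > 0.05)
    if normal:
        res = stats.ttest_rel(x, y)
        test = "paired_t"
    else:
        res = stats.wilcoxon(x, y)
        test = "signed_rank"
    p_adj = min(1.0, float(res.pvalue) * n_comparisons)
    return {"test": test, "statistic": float(res.statistic),
            "p_raw": float(res.pvalue), "p_adj": p_adj, "normal": normal,
            "jarque_bera_p": float(jb_p),
            "significant": bool(p_adj < alpha),
            "mean_diff": float(d.mean())}
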