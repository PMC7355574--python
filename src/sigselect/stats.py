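"""Small shared statistical utilities."""

from __future__ import annotations

import numpy as np
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

__all__ = ["t_critical_value", "bh_adjust"]


def t_critical_value(alpha: float, df: int) -> float:
    """Two-tailed Student-t critical value at significance level ``alpha``.

    E.g. alpha=0.05, df=90 -> 1.987 (3 d.p.), the threshold against which a
    paired t statistic is judged when pooling two sample subgroups.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    return float(_st.t.ppf(1.0 - alpha / 2.0, df))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (FDR)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
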