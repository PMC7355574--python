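"""Mann-Whitney differential-expression screening between two groups.

The rank-sum test asks, gene by gene, whether expression in one group tends
to exceed the other, without assuming a distributional form — appropriate
for small, skewed 2^-ddCt samples. The exact null is enumerated when the
product of group sizes is at most 400 and the data are tie-free; otherwise
the normal approximation with tie and continuity corrections is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .expression import ExpressionMatrix
from .stats import bh_adjust

__all__ = ["UnivariateResult", "mann_whitney_screen", "top_k_by_p", "results_to_frame"]

EXACT_MAX_PRODUCT = 400
DEFAULT_ALPHA_LEVELS = (0.05, 0.01, 0.0001)
_RATIO_PSEUDOCOUNT = 1e-6


@dataclass
class UnivariateResult:
    gene_id: str
    u_statistic: float
    p_value: float
    median_a: float
    median_b: float
    direction: str  # up_in_b | down_in_b | tie
    tier: float | None = None  # smallest alpha level reached, None if n.s.
    p_adj_bh: float | None = None
    n_a: int = 0
    n_b: int = 0
    method: str = "exact"

    @property
    def log2_median_ratio(self) -> float:
        return math.log2(
            (self.median_b + _RATIO_PSEUDOCOUNT) / (self.median_a + _RATIO_PSEUDOCOUNT)
        )


def _test_one_gene(a: np.ndarray, b: np.ndarray) -> tuple[float, float, str]:
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(a) * len(b) <= EXACT_MAX_PRODUCT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue), method


def mann_whitney_screen(
    em: ExpressionMatrix,
    class_pair: tuple[str, str],
    alpha_levels=DEFAULT_ALPHA_LEVELS,
) -> list[UnivariateResult]:
    """Two-sided per-gene Mann-Whitney test between the two classes.

    Returns results sorted by ascending p-value. Each result is annotated
    with the strictest significance tier reached among ``alpha_levels`` and
    a Benjamini-Hochberg adjusted p-value. Missing values are dropped per
    gene; both groups need at least 2 observations.
    """
    class_a, class_b = class_pair
    samples_a = em.samples_of(class_a)
    samples_b = em.samples_of(class_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"each group needs >=2 samples; got {class_a}:{len(samples_a)}, "
            f"{class_b}:{len(samples_b)}"
        )
    alpha_levels = sorted(alpha_levels, reverse=True)  # loosest first

    results: list[UnivariateResult] = []
    for gene in em.gene_ids:
        a = em.values.loc[gene, samples_a].astype(float).dropna().to_numpy()
        b = em.values.loc[gene, samples_b].astype(float).dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(
                f"gene {gene!r} has <2 non-missing values in a group"
            )
        u, p, method = _test_one_gene(a, b)
        med_a, med_b = float(np.median(a)), float(np.median(b))
        if med_b > med_a:
            direction = "up_in_b"
        elif med_b < med_a:
            direction = "down_in_b"
        else:
            direction = "tie"
        tier = None
        for alpha in alpha_levels:
            if p <= alpha:
                tier = alpha
        results.append(
            UnivariateResult(
                gene_id=str(gene),
                u_statistic=u,
                p_value=p,
                median_a=med_a,
                median_b=med_b,
                direction=direction,
                tier=tier,
                n_a=len(a),
                n_b=len(b),
                method=method,
            )
        )

    padj = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, padj):
        r.p_adj_bh = float(q)
    results.sort(key=lambda r: (r.p_value, r.gene_id))
    return results


def top_k_by_p(results: list[UnivariateResult], k: int) -> list[UnivariateResult]:
    """First k results by ascending p; ties broken by |log2 median ratio|
    (descending), then gene symbol."""
    if k > len(results):
        raise ValueError(f"k={k} exceeds number of genes {len(results)}")
    ordered = sorted(
        results,
        key=lambda r: (r.p_value, -abs(r.log2_median_ratio), r.gene_id),
    )
    return ordered[:k]


def results_to_frame(results: list[UnivariateResult]) -> pd.DataFrame:
    """Tabular view for TSV export."""
    return pd.DataFrame(
        {
            "gene": [r.gene_id for r in results],
            "U": [r.u_statistic for r in results],
            "p": [r.p_value for r in results],
            "p_adj_BH": [r.p_adj_bh for r in results],
            "median_A": [r.median_a for r in results],
            "median_B": [r.median_b for r in results],
            "direction": [r.direction for r in results],
            "tier": [r.tier for r in results],
        }
    )
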