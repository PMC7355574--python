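"""Synthetic qPCR-panel datasets with known ground truth.

The generator emulates a two-class relative-quantification study: a panel
of genes (91 by default) measured in two modest sample groups (12 vs 29 by
default), where a known subset of "planted" genes carries a true between-
class shift on the log2 expression scale, some genes co-vary in correlated
blocks, and technical noise acts on the Ct (cycle) scale — i.e.
multiplicatively on expression. Data are emitted through a simulated Ct
pipeline (gene-specific baseline Ct, constant housekeeping gene, per-gene
calibrator reference) and converted by the package's own 2^-ddCt
quantification, so synthetic data enter the pipeline exactly as study
exports would.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import (
    CtTable,
    ExpressionMatrix,
    compute_relative_expression,
    write_expression_csv,
)

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "generate",
    "make_study_shaped_benchmark",
    "BENCHMARK_COMPARISONS",
]

HOUSEKEEPING_ID = "HK"
HOUSEKEEPING_CT = 20.0

# (class size A, class size B, planted gene count) for the four study-shaped
# two-class comparisons of cell sources before/after transplantation.
BENCHMARK_COMPARISONS: dict[str, tuple[int, int, int]] = {
    "ucb_vs_adult": (12, 15, 6),
    "ucb_vs_ucbt": (12, 13, 52),
    "adult_vs_hsct": (15, 29, 62),
    "ucbt_vs_hsct": (13, 29, 49),
}


@dataclass
class SyntheticSpec:
    """Generative parameters.

    effect_size is the mean log2 expression shift of planted genes between
    classes (2.0 = a 4-fold change, strong but within the range qPCR panels
    report). block_structure lists (block size, within-block correlation)
    pairs of co-regulated genes; ct_noise_sd is technical noise in PCR
    cycles (0.25 cycles ~ 19% multiplicative noise).
    """

    n_genes: int = 91
    n_per_class: tuple[int, int] = (12, 29)
    planted_genes: int = 10
    effect_size: float = 2.0
    block_structure: Sequence[tuple[int, float]] = ((8, 0.6), (8, 0.6), (8, 0.4))
    ct_noise_sd: float = 0.25
    biological_sd: float = 1.0
    seed: int = 0
    class_names: tuple[str, str] = ("groupA", "groupB")

    def __post_init__(self) -> None:
        if self.planted_genes > self.n_genes:
            raise ValueError("planted_genes cannot exceed n_genes")
        if any(s <= 0 for s in self.n_per_class) or self.n_genes <= 0:
            raise ValueError("all sizes must be positive")
        for size, rho in self.block_structure:
            if size <= 0:
                raise ValueError("block sizes must be positive")
            if not 0 <= rho < 1:
                raise ValueError(
                    f"within-block correlation must be in [0, 1); got {rho}"
                )
        if sum(s for s, _ in self.block_structure) > self.n_genes:
            raise ValueError("block structure exceeds the gene panel")
        if self.ct_noise_sd < 0 or self.biological_sd <= 0:
            raise ValueError("noise scales must be positive")


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    truth: list[tuple[str, str]]  # (gene id, direction up|down in class B)
    spec: SyntheticSpec
    ct_table: CtTable = field(repr=False, default=None)

    @property
    def truth_genes(self) -> list[str]:
        return [g for g, _ in self.truth]


def _block_covariance(spec: SyntheticSpec) -> np.ndarray:
    """Unit-variance covariance with equicorrelated diagonal blocks."""
    cov = np.eye(spec.n_genes)
    start = 0
    for size, rho in spec.block_structure:
        block = np.full((size, size), rho)
        np.fill_diagonal(block, 1.0)
        # equicorrelation with rho in [0,1) is positive definite by construction
        cov[start : start + size, start : start + size] = block
        start += size
    return cov * spec.biological_sd**2


def generate(spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Draw one dataset; a fixed seed gives bit-identical output."""
    if spec is None:
        spec = SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    n_a, n_b = spec.n_per_class
    n = n_a + n_b
    gene_ids = [f"G{i + 1:03d}" for i in range(spec.n_genes)]
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    labels = [spec.class_names[0]] * n_a + [spec.class_names[1]] * n_b

    planted_idx = rng.choice(spec.n_genes, size=spec.planted_genes, replace=False)
    signs = rng.choice([-1.0, 1.0], size=spec.planted_genes)

    mu = rng.normal(0.0, 2.0, size=spec.n_genes)  # gene-level baseline log2 level
    cov = _block_covariance(spec)
    chol = np.linalg.cholesky(cov)
    latent = mu[:, None] + chol @ rng.standard_normal((spec.n_genes, n))
    shift = np.zeros(spec.n_genes)
    shift[planted_idx] = signs * spec.effect_size
    latent[:, n_a:] += shift[:, None]  # class B carries the planted effect

    # Ct export: higher abundance -> lower cycle count; technical noise in cycles
    baseline_ct = rng.uniform(24.0, 32.0, size=spec.n_genes)
    ct = (
        baseline_ct[:, None]
        - latent
        + rng.normal(0.0, spec.ct_noise_sd, size=(spec.n_genes, n))
    )
    ct_df = pd.DataFrame(ct, index=gene_ids, columns=sample_ids)
    ct_df.loc[HOUSEKEEPING_ID] = HOUSEKEEPING_CT
    calibrator = pd.Series(baseline_ct - HOUSEKEEPING_CT, index=gene_ids)
    table = CtTable(
        ct=ct_df, housekeeping_gene=HOUSEKEEPING_ID, calibrator=calibrator
    )

    em = compute_relative_expression(table)
    em.class_labels = pd.Series(labels, index=sample_ids)
    truth = [
        (gene_ids[i], "up" if s > 0 else "down")
        for i, s in sorted(zip(planted_idx, signs))
    ]
    return SyntheticDataset(expression=em, truth=truth, spec=spec, ct_table=table)


def make_study_shaped_benchmark(
    comparison: str, seed: int = 0, **overrides
) -> SyntheticDataset:
    """Dataset shaped like one of the four study comparisons.

    Class sizes match the study groups (12 vs 15, 12 vs 13, 15 vs 29,
    13 vs 29) and planted-gene counts loosely match the reported signature
    sizes (6, 52, 62, 49), capped at n_genes - 1.
    """
    if comparison not in BENCHMARK_COMPARISONS:
        raise ValueError(
            f"unknown comparison {comparison!r}; valid names: "
            f"{sorted(BENCHMARK_COMPARISONS)}"
        )
    n_a, n_b, planted = BENCHMARK_COMPARISONS[comparison]
    kwargs = dict(n_per_class=(n_a, n_b), planted_genes=planted, seed=seed)
    kwargs.update(overrides)
    n_genes = kwargs.get("n_genes", 91)
    kwargs["planted_genes"] = min(kwargs["planted_genes"], n_genes - 1)
    return generate(SyntheticSpec(**kwargs))


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write expression TSV, annotation CSV and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression_csv(
        ds.expression, outdir / "expression.csv", outdir / "annotation.csv"
    )
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "planted": [{"gene": g, "direction": d} for g, d in ds.truth],
                "spec": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(ds.spec).items()
                },
            },
            fh,
            indent=2,
        )
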