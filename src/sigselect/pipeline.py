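"""Nested cross-validation driving sparse signature selection.

The outer K-fold loop estimates generalization performance; within each
outer training set an inner K-fold loop picks the regularization pair
(tau*, lambda*) minimizing mean validation misclassification (ties prefer
sparser models: larger tau, then smaller lambda). The model refit on the
full outer-training set at (tau*, lambda*) contributes one list of
selected genes (non-zero weights) and its predictions on the held-out
outer fold. A gene's frequency score is the percentage of outer folds
selecting it; genes at or above the frequency threshold (50% by default)
form the signature. Accuracy and MCC are computed from the pooled
outer-test predictions, so every reported prediction comes from a model
that never saw that sample — standardization included.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, KFold

from . import solver
from .expression import ExpressionMatrix, build_design_matrix, export_heatmap
from .metrics import accuracy, confusion, mcc

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfiguration",
    "FoldResult",
    "SignatureEntry",
    "Signature",
    "run_nested_cv",
    "direction_annotate",
    "frequency_threshold_scan",
    "write_outputs",
]

DEFAULT_LAMBDA_GRID = (0.01, 0.1, 1.0, 10.0)


@dataclass
class CVConfiguration:
    """Knobs of the nested-CV signature selection.

    tau_grid=None builds a decreasing geometric grid of ``n_tau`` values
    from tau_max (smallest l1 weight emptying the model on the full data)
    down to tau_max/tau_ratio.
    """

    k_outer: int = 5
    k_inner: int = 4
    tau_grid: Sequence[float] | None = None
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID
    n_tau: int = 20
    tau_ratio: float = 1000.0
    seed: int = 0
    frequency_threshold: float = 50.0
    stratified: bool = True
    refit: bool = True
    transform: str = "log2"
    pseudocount: float = 1e-6
    tol: float = 1e-6
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if self.k_outer < 2 or self.k_inner < 2:
            raise ValueError("k_outer and k_inner must each be >= 2")
        if not 0 < self.frequency_threshold <= 100:
            raise ValueError("frequency_threshold must be in (0, 100]")
        if self.tau_grid is not None and len(self.tau_grid) == 0:
            raise ValueError("tau_grid must be non-empty")
        if len(self.lambda_grid) == 0:
            raise ValueError("lambda_grid must be non-empty")


@dataclass
class FoldResult:
    fold_index: int
    tau_star: float
    lambda_star: float
    selected_genes: list[str]
    test_sample_ids: list[str]
    true_labels: list[int]
    predicted_labels: list[int]
    scores: list[float]


@dataclass
class SignatureEntry:
    gene_id: str
    frequency_percent: float
    direction: str | None = None  # up | down | tie (relative to class order)


@dataclass
class Signature:
    entries: list[SignatureEntry]
    accuracy_percent: float
    mcc: float
    comparison_name: str
    frequency_threshold: float
    class_map: dict[str, int] = field(default_factory=dict)
    per_fold_accuracy: list[float] = field(default_factory=list)
    per_fold_mcc: list[float] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]


def _splitter(k: int, stratified: bool, seed: int):
    cls = StratifiedKFold if stratified else KFold
    return cls(n_splits=k, shuffle=True, random_state=seed)


def _fit_eval_grid(em, class_pair, train_ids, val_ids, tau_grid, lambda_grid, config):
    """Misclassification counts and square losses on one inner split.

    Both are accumulated for every (tau, lambda): misclassification is the
    primary model-selection criterion, but on validation folds of a handful
    of samples it is a coarse integer and ties are pervasive, so the square
    loss of the real-valued scores against the +-1 labels — the quantity
    the model itself minimizes — disambiguates before the sparsity
    preference is applied.
    """
    dm = build_design_matrix(
        em, class_pair, transform=config.transform,
        pseudocount=config.pseudocount, fit_samples=train_ids,
    )
    tr = dm.rows(train_ids)
    va = dm.rows(val_ids)
    X_tr, Y_tr = dm.X[tr], dm.Y[tr]
    X_va, Y_va = dm.X[va], dm.Y[va]
    n = X_tr.shape[0]
    gram = solver.gram_spectral_norm(X_tr)
    errors = np.empty((len(tau_grid), len(lambda_grid)))
    sq_losses = np.empty((len(tau_grid), len(lambda_grid)))
    for j, lam in enumerate(lambda_grid):
        sigma = lam + gram / n
        beta = None
        for i, tau in enumerate(tau_grid):
            model = solver.fit_l1l2(
                X_tr, Y_tr, tau, lam, tol=config.tol,
                max_iter=config.max_iter, beta0=beta, sigma=sigma,
            )
            beta = model.beta
            used = model
            if config.refit:
                used = solver.refit_on_support(X_tr, Y_tr, model.support, lam)
            pred, scores = solver.predict(used, X_va)
            errors[i, j] = np.sum(pred != Y_va)
            sq_losses[i, j] = np.sum((Y_va - scores) ** 2)
    return errors, sq_losses


def run_nested_cv(
    em: ExpressionMatrix,
    class_pair: tuple[str, str],
    config: CVConfiguration | None = None,
    comparison_name: str | None = None,
) -> tuple[list[FoldResult], Signature]:
    """Full stability-selection run for one two-class comparison."""
    if config is None:
        config = CVConfiguration()
    class_a, class_b = class_pair
    samples_a = em.samples_of(class_a)
    samples_b = em.samples_of(class_b)
    if config.stratified and min(len(samples_a), len(samples_b)) < config.k_outer:
        raise ValueError(
            f"stratified outer CV needs >= {config.k_outer} samples per class; "
            f"got {class_a}:{len(samples_a)}, {class_b}:{len(samples_b)}"
        )
    samples = np.array(
        [s for s in em.sample_ids if s in set(samples_a) | set(samples_b)]
    )
    strat = np.array([em.class_labels[s] for s in samples])

    # tau grid from the full comparison data (scale of the problem), once
    if config.tau_grid is None:
        dm_full = build_design_matrix(
            em, class_pair, transform=config.transform,
            pseudocount=config.pseudocount,
        )
        tau_grid = solver.make_tau_grid(
            dm_full.X, dm_full.Y, n_values=config.n_tau, ratio=config.tau_ratio
        )
    else:
        tau_grid = np.asarray(sorted(config.tau_grid, reverse=True), dtype=float)
    lambda_grid = np.asarray(sorted(config.lambda_grid), dtype=float)

    rng = np.random.default_rng(config.seed)
    outer = _splitter(config.k_outer, config.stratified, config.seed)
    fold_results: list[FoldResult] = []
    for fold_index, (tr_idx, te_idx) in enumerate(outer.split(samples, strat)):
        outer_train = list(samples[tr_idx])
        outer_test = list(samples[te_idx])
        tr_strat = strat[tr_idx]
        if len(set(tr_strat)) < 2:
            raise ValueError(
                "an outer training set contains a single class; use a smaller k_outer"
            )

        inner_seed = int(rng.integers(2**31))
        inner = _splitter(config.k_inner, config.stratified, inner_seed)
        total_err = np.zeros((len(tau_grid), len(lambda_grid)))
        total_sq = np.zeros((len(tau_grid), len(lambda_grid)))
        for in_tr, in_va in inner.split(np.array(outer_train), tr_strat):
            train_ids = [outer_train[i] for i in in_tr]
            val_ids = [outer_train[i] for i in in_va]
            errs, sqs = _fit_eval_grid(
                em, class_pair, train_ids, val_ids, tau_grid, lambda_grid, config
            )
            total_err += errs
            total_sq += sqs

        # primary: misclassification; among its ties: validation square
        # loss; residual ties -> larger tau (sparser), then smaller lambda
        best = min(
            (
                (total_err[i, j], total_sq[i, j], -tau_grid[i], lambda_grid[j], i, j)
                for i in range(len(tau_grid))
                for j in range(len(lambda_grid))
            )
        )
        tau_star, lambda_star = tau_grid[best[-2]], lambda_grid[best[-1]]

        dm = build_design_matrix(
            em, class_pair, transform=config.transform,
            pseudocount=config.pseudocount, fit_samples=outer_train,
        )
        tr = dm.rows(outer_train)
        te = dm.rows(outer_test)
        model = solver.fit_l1l2(
            dm.X[tr], dm.Y[tr], tau_star, lambda_star,
            tol=config.tol, max_iter=config.max_iter,
        )
        selected = [dm.gene_ids[i] for i in model.support]
        used = model
        if config.refit:
            used = solver.refit_on_support(
                dm.X[tr], dm.Y[tr], model.support, lambda_star
            )
        pred, scores = solver.predict(used, dm.X[te])
        fold_results.append(
            FoldResult(
                fold_index=fold_index,
                tau_star=float(tau_star),
                lambda_star=float(lambda_star),
                selected_genes=sorted(selected),
                test_sample_ids=outer_test,
                true_labels=[int(v) for v in dm.Y[te]],
                predicted_labels=[int(v) for v in pred],
                scores=[float(v) for v in scores],
            )
        )

    freq = _gene_frequencies(fold_results, config.k_outer)
    entries = [
        SignatureEntry(gene_id=g, frequency_percent=f)
        for g, f in freq.items()
        if f >= config.frequency_threshold
    ]
    entries.sort(key=lambda e: (-e.frequency_percent, e.gene_id))

    y_true = np.concatenate([fr.true_labels for fr in fold_results])
    y_pred = np.concatenate([fr.predicted_labels for fr in fold_results])
    pooled = confusion(y_true, y_pred)
    per_acc, per_mcc = [], []
    for fr in fold_results:
        c = confusion(fr.true_labels, fr.predicted_labels)
        per_acc.append(accuracy(c))
        per_mcc.append(mcc(c))

    signature = Signature(
        entries=entries,
        accuracy_percent=accuracy(pooled),
        mcc=mcc(pooled),
        comparison_name=comparison_name or f"{class_a}_vs_{class_b}",
        frequency_threshold=config.frequency_threshold,
        class_map={class_a: -1, class_b: +1},
        per_fold_accuracy=per_acc,
        per_fold_mcc=per_mcc,
    )
    signature = direction_annotate(signature, em, class_pair)
    return fold_results, signature


def _gene_frequencies(fold_results: list[FoldResult], k_outer: int) -> dict[str, float]:
    counts: dict[str, int] = {}
    for fr in fold_results:
        for g in fr.selected_genes:
            counts[g] = counts.get(g, 0) + 1
    return {g: 100.0 * c / k_outer for g, c in counts.items()}


def direction_annotate(
    signature: Signature, em: ExpressionMatrix, class_pair: tuple[str, str]
) -> Signature:
    """Mark each signature gene up/down in the second class vs the first.

    'up' = median expression higher in the second class of the pair; equal
    medians are flagged 'tie'.
    """
    class_a, class_b = class_pair
    sa = em.samples_of(class_a)
    sb = em.samples_of(class_b)
    for entry in signature.entries:
        if entry.gene_id not in em.values.index:
            raise KeyError(f"signature gene {entry.gene_id!r} not in matrix")
        med_a = float(em.values.loc[entry.gene_id, sa].median())
        med_b = float(em.values.loc[entry.gene_id, sb].median())
        if med_b > med_a:
            entry.direction = "up"
        elif med_b < med_a:
            entry.direction = "down"
        else:
            entry.direction = "tie"
    return signature


def frequency_threshold_scan(
    fold_results: list[FoldResult],
) -> pd.DataFrame:
    """Genes-at-or-above-threshold counts across the attainable frequencies.

    Emitted so the slope change of n_selected vs threshold can be
    inspected; the pipeline's operating default stays 50%.
    """
    if not fold_results:
        raise ValueError("need at least one fold")
    k = len(fold_results)
    freq = _gene_frequencies(fold_results, k)
    thresholds = [100.0 * i / k for i in range(1, k + 1)]
    rows = [
        {"threshold": t, "n_selected": sum(1 for f in freq.values() if f >= t)}
        for t in thresholds
    ]
    return pd.DataFrame(rows)


def write_outputs(
    outdir,
    fold_results: list[FoldResult],
    signature: Signature,
    em: ExpressionMatrix | None = None,
) -> None:
    """Write signature TSV, fold-results JSON, metrics JSON, threshold scan
    TSV and (when the matrix is given) the signature heatmap TSV+sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "gene": [e.gene_id for e in signature.entries],
            "frequency_percent": [e.frequency_percent for e in signature.entries],
            "direction": [e.direction for e in signature.entries],
        }
    ).to_csv(outdir / "signature.tsv", sep="\t", index=False)
    with open(outdir / "fold_results.json", "w") as fh:
        json.dump([asdict(fr) for fr in fold_results], fh, indent=2)
    y_true = np.concatenate([fr.true_labels for fr in fold_results])
    y_pred = np.concatenate([fr.predicted_labels for fr in fold_results])
    c = confusion(y_true, y_pred)
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(
            {
                "comparison": signature.comparison_name,
                "class_map": signature.class_map,
                "accuracy_percent": signature.accuracy_percent,
                "mcc": signature.mcc,
                "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
                "per_fold": [
                    {"accuracy_percent": a, "mcc": m}
                    for a, m in zip(
                        signature.per_fold_accuracy, signature.per_fold_mcc
                    )
                ],
            },
            fh,
            indent=2,
        )
    frequency_threshold_scan(fold_results).to_csv(
        outdir / "threshold_scan.tsv", sep="\t", index=False
    )
    if em is not None and signature.entries:
        sub = ExpressionMatrix(
            values=em.values.loc[signature.gene_ids],
            class_labels=em.class_labels,
        )
        export_heatmap(
            sub, outdir / "heatmap.tsv", outdir / "heatmap_order.json"
        )
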