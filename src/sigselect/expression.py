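"""Data model and I/O for qPCR-panel expression matrices.

Relative quantification follows the standard comparative-Ct scheme: for each
gene g and sample s,

    dCt(g, s)  = Ct(g, s) - Ct(housekeeping, s)
    ddCt(g, s) = dCt(g, s) - dCt_calibrator(g)
    value      = 2 ** (-ddCt)

so a sample identical to the calibrator has value 1 for every gene, and the
values are nonnegative fold-change-like quantities relative to a common
reference RNA.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CtTable",
    "ExpressionMatrix",
    "DesignMatrix",
    "compute_relative_expression",
    "read_expression_csv",
    "write_expression_csv",
    "build_design_matrix",
    "scale_for_heatmap",
    "export_heatmap",
]


@dataclass
class CtTable:
    """Cycle-threshold table (genes x samples) with housekeeping/calibrator info.

    ``calibrator`` is either a sample id present in the table (its per-gene
    dCt becomes the reference) or a per-gene dCt reference vector
    (pd.Series indexed by gene).
    """

    ct: pd.DataFrame
    housekeeping_gene: str
    calibrator: str | pd.Series

    def __post_init__(self) -> None:
        if self.ct.index.duplicated().any():
            dup = self.ct.index[self.ct.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids in Ct table: {dup}")
        if self.ct.columns.duplicated().any():
            dup = self.ct.columns[self.ct.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in Ct table: {dup}")
        if self.housekeeping_gene not in self.ct.index:
            raise ValueError(
                f"housekeeping gene {self.housekeeping_gene!r} not in Ct table"
            )
        hk = self.ct.loc[self.housekeeping_gene]
        if hk.isna().any():
            bad = hk.index[hk.isna()].tolist()
            raise ValueError(
                f"housekeeping gene {self.housekeeping_gene!r} has missing Ct "
                f"in samples {bad}"
            )
        if isinstance(self.calibrator, str):
            if self.calibrator not in self.ct.columns:
                raise ValueError(
                    f"calibrator sample {self.calibrator!r} not in Ct table"
                )
        else:
            self.calibrator = pd.Series(self.calibrator, dtype=float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.columns)


@dataclass
class ExpressionMatrix:
    """Relative expression values (2^-ddCt scale, genes x samples).

    ``class_labels`` maps sample id -> class name; it may be None for
    matrices not yet annotated (e.g. fresh from relative quantification).
    """

    values: pd.DataFrame
    class_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        finite = self.values.to_numpy(dtype=float)
        finite = finite[np.isfinite(finite)]
        if (finite < 0).any():
            raise ValueError("relative expression values must be nonnegative")
        if self.class_labels is not None:
            self.class_labels = pd.Series(self.class_labels).astype(str)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def classes(self) -> list[str]:
        if self.class_labels is None:
            return []
        return sorted(self.class_labels.unique())

    def samples_of(self, class_name: str) -> list[str]:
        """Sample ids with the given class label, in matrix column order."""
        if self.class_labels is None:
            raise ValueError("expression matrix has no class annotation")
        wanted = {s for s, c in self.class_labels.items() if c == class_name}
        return [s for s in self.sample_ids if s in wanted]


@dataclass
class DesignMatrix:
    """Standardized samples-x-genes matrix with +-1 labels for the classifier.

    Standardization parameters (per-gene center/scale) are learned from
    ``fit_samples`` only and stored, so test samples can be projected into
    the same coordinates without leakage.
    """

    X: np.ndarray
    Y: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    center: np.ndarray
    scale: np.ndarray
    class_map: dict[str, int]
    fit_samples: list[str]
    zero_variance_genes: list[str] = field(default_factory=list)
    transform: str = "log2"
    pseudocount: float = 1e-6

    def rows(self, sample_ids: Sequence[str]) -> np.ndarray:
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return np.asarray(idx, dtype=int)


def compute_relative_expression(ct: CtTable) -> ExpressionMatrix:
    """2^-ddCt relative quantification against housekeeping gene + calibrator.

    The housekeeping row is excluded from the output. Missing Ct values
    propagate to missing expression values.
    """
    hk = ct.ct.loc[ct.housekeeping_gene]
    dct = ct.ct.sub(hk, axis=1)
    if isinstance(ct.calibrator, str):
        cal = dct[ct.calibrator]
    else:
        cal = ct.calibrator.reindex(ct.ct.index)
        missing = cal.index[cal.isna() & (cal.index != ct.housekeeping_gene)]
        if len(missing):
            raise ValueError(
                f"calibrator dCt reference missing for genes: {list(missing)}"
            )
    ddct = dct.sub(cal, axis=0)
    values = np.power(2.0, -ddct)
    values = values.drop(index=ct.housekeeping_gene)
    return ExpressionMatrix(values=values)


def read_expression_csv(
    path,
    annotation_path=None,
    orientation: str = "genes_in_rows",
    sep: str | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression matrix, optionally with a sample annotation.

    Non-numeric cells become missing values. The annotation file is a
    two-column table (sample_id, class). ``orientation`` is
    ``genes_in_rows`` (default) or ``samples_in_rows``.
    """
    if sep is None:
        with open(path) as fh:
            first = fh.readline()
        sep = "\t" if "\t" in first else ","
    # round_trip parsing keeps finite values bit-exact across write/read
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if orientation == "samples_in_rows":
        df = df.T
    elif orientation != "genes_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    if df.index.duplicated().any():
        dup = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicated gene rows: {dup}")
    df = df.apply(pd.to_numeric, errors="coerce")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    labels = None
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path)
        if ann.shape[1] < 2:
            raise ValueError("annotation file needs (sample_id, class) columns")
        labels = pd.Series(
            ann.iloc[:, 1].astype(str).values, index=ann.iloc[:, 0].astype(str)
        )
        unlabeled = [s for s in df.columns if s not in labels.index]
        if unlabeled:
            raise ValueError(
                f"samples in matrix without class annotation: {unlabeled}"
            )
        extra = [s for s in labels.index if s not in df.columns]
        if extra:
            logger.warning("annotation rows for unknown samples ignored: %s", extra)
            labels = labels.drop(index=extra)
    return ExpressionMatrix(values=df, class_labels=labels)


def write_expression_csv(em: ExpressionMatrix, path, annotation_path=None) -> None:
    em.values.to_csv(path)
    if annotation_path is not None and em.class_labels is not None:
        pd.DataFrame(
            {"sample_id": em.class_labels.index, "class": em.class_labels.values}
        ).to_csv(annotation_path, index=False)


def build_design_matrix(
    em: ExpressionMatrix,
    class_pair: tuple[str, str],
    transform: str = "log2",
    pseudocount: float = 1e-6,
    fit_samples: Sequence[str] | None = None,
    max_missing_frac: float = 0.2,
) -> DesignMatrix:
    """Assemble the classifier input for a two-class comparison.

    Samples become rows; the first class of ``class_pair`` maps to -1 and
    the second to +1. Expression is optionally log2(value + pseudocount)
    transformed, then per-gene centered/scaled with statistics computed on
    ``fit_samples`` only (all comparison samples by default). Genes missing
    in more than ``max_missing_frac`` of the comparison samples are dropped;
    remaining missing values are imputed with the fit-sample gene median.
    Zero-variance genes on the fit samples get scale 1 and are flagged.
    """
    class_a, class_b = class_pair
    samples_a = em.samples_of(class_a)
    samples_b = em.samples_of(class_b)
    if not samples_a or not samples_b:
        empty = class_a if not samples_a else class_b
        raise ValueError(f"class {empty!r} has no samples")
    samples = [s for s in em.sample_ids if s in set(samples_a) | set(samples_b)]
    if fit_samples is None:
        fit_samples = samples
    else:
        fit_samples = list(fit_samples)
        unknown = set(fit_samples) - set(samples)
        if unknown:
            raise ValueError(f"fit_samples not in comparison: {sorted(unknown)}")

    vals = em.values[samples].astype(float)
    missing_frac = vals.isna().mean(axis=1)
    dropped = missing_frac.index[missing_frac > max_missing_frac].tolist()
    if dropped:
        logger.warning(
            "dropping %d genes missing in >%.0f%% of samples: %s",
            len(dropped), 100 * max_missing_frac, dropped,
        )
        vals = vals.drop(index=dropped)

    if transform == "log2":
        mat = np.log2(vals + pseudocount)
    elif transform == "none":
        mat = vals
    else:
        raise ValueError(f"unknown transform {transform!r}")

    fit = mat[fit_samples]
    med = fit.median(axis=1, skipna=True).fillna(0.0)
    mat = mat.apply(lambda col: col.fillna(med))

    fit = mat[fit_samples]
    center = fit.mean(axis=1).to_numpy()
    scale = fit.std(axis=1, ddof=1).to_numpy()
    if len(fit_samples) < 2:
        scale = np.zeros_like(center)
    zero_var = scale == 0
    scale = np.where(zero_var, 1.0, scale)
    flagged = [g for g, z in zip(mat.index, zero_var) if z]

    X = ((mat.to_numpy().T - center) / scale).astype(float)
    label_of = {class_a: -1, class_b: +1}
    Y = np.array([label_of[em.class_labels[s]] for s in samples], dtype=float)
    return DesignMatrix(
        X=X,
        Y=Y,
        gene_ids=list(mat.index),
        sample_ids=samples,
        center=center,
        scale=scale,
        class_map=label_of,
        fit_samples=list(fit_samples),
        zero_variance_genes=flagged,
        transform=transform,
        pseudocount=pseudocount,
    )


def scale_for_heatmap(
    em: ExpressionMatrix, class_order: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-gene z-scores (mean 0, sample SD 1) for heatmap export.

    Constant rows become all zeros. Columns are ordered by sample group
    when the matrix is annotated (``class_order`` controls group order).
    """
    if em.values.shape[1] < 2:
        raise ValueError("heatmap scaling needs at least 2 samples")
    vals = em.values.astype(float)
    center = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    sd = sd.where(sd > 0, 1.0)
    scaled = vals.sub(center, axis=0).div(sd, axis=0)
    if em.class_labels is not None:
        order = class_order if class_order is not None else em.classes()
        cols: list[str] = []
        for cls in order:
            cols.extend(em.samples_of(cls))
        cols.extend([s for s in em.sample_ids if s not in set(cols)])
        scaled = scaled[cols]
    return scaled


def export_heatmap(em: ExpressionMatrix, tsv_path, sidecar_path=None, **kwargs) -> None:
    """Write scaled heatmap values as TSV plus a JSON sidecar of row/col order."""
    scaled = scale_for_heatmap(em, **kwargs)
    scaled.to_csv(tsv_path, sep="\t")
    if sidecar_path is not None:
        meta = {
            "row_order": list(scaled.index),
            "col_order": list(scaled.columns),
        }
        if em.class_labels is not None:
            meta["col_classes"] = [em.class_labels[s] for s in scaled.columns]
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)
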