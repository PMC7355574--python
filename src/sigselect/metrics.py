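"""Binary-classification metrics: confusion counts, accuracy, MCC.

Classes are coded -1 (negative) and +1 (positive). True positives are
positive samples predicted +1; false positives are negatives predicted +1,
and so on. The Matthews Correlation Coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

ranges over [-1, 1], equals the Pearson correlation between the true and
predicted +-1 label vectors, and is robust to class imbalance; a random
classifier scores about 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ConfusionCounts", "confusion", "accuracy", "mcc"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def degenerate(self) -> bool:
        """True when a confusion-table margin is empty (MCC denominator 0)."""
        return 0 in (
            self.tp + self.fp,
            self.tp + self.fn,
            self.tn + self.fp,
            self.tn + self.fn,
        )


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    """Tally a confusion table from +-1 label vectors."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    for arr, name in ((t, "true"), (p, "predicted")):
        bad = set(np.unique(arr)) - {-1, 1}
        if bad:
            raise ValueError(f"{name} labels outside {{-1,+1}}: {sorted(bad)}")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        tn=int(np.sum((t == -1) & (p == -1))),
        fp=int(np.sum((t == -1) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == -1))),
    )


def accuracy(c: ConfusionCounts) -> float:
    """Percentage of correctly classified samples, in [0, 100]."""
    if c.total == 0:
        raise ValueError("accuracy undefined on an empty confusion table")
    return 100.0 * (c.tp + c.tn) / c.total


def mcc(c: ConfusionCounts) -> float:
    """Matthews Correlation Coefficient; 0 (flagged) when a margin is empty."""
    if c.total == 0:
        raise ValueError("MCC undefined on an empty confusion table")
    if c.degenerate:
        logger.warning("MCC denominator has a zero factor; returning 0 by convention")
        return 0.0
    num = c.tp * c.tn - c.fp * c.fn
    den = math.sqrt(
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    return num / den
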