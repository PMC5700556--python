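"""Per-tissue segmentation evaluation against a pixel-wise ground truth.

Each tissue is scored one-vs-rest: a pixel is a true positive when both the
prediction and the truth assign it to the tissue, and so on.  From the
confusion counts the standard rates follow:

    sensitivity = TP / (TP + FN)
    specificity = TN / (FP + TN)
    accuracy    = (TP + TN) / (TP + TN + FP + FN)

A metric whose denominator is zero (e.g. sensitivity of a tissue absent
from both truth and prediction) is reported as None rather than silently
defaulting to 0 or 1, so averages are never corrupted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .labels import BRAIN_TISSUES, TISSUE_NAMES

__all__ = ["ConfusionCounts", "TissueMetrics", "confusion_counts",
           "evaluate", "evaluate_tissues"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class TissueMetrics:
    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]


def confusion_counts(pred, truth, eval_mask=None) -> ConfusionCounts:
    """Tally TP/TN/FP/FN of a boolean prediction against boolean truth.

    ``eval_mask`` restricts the tally (e.g. to the brain mask); by default
    every pixel is evaluated.
    """
    p = np.asarray(pred, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise ValueError("prediction and truth shapes differ")
    if eval_mask is not None:
        m = np.asarray(eval_mask, dtype=bool)
        if m.shape != p.shape:
            raise ValueError("eval_mask shape differs")
        p, t = p[m], t[m]
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def evaluate(counts: ConfusionCounts) -> TissueMetrics:
    """Sensitivity, specificity and accuracy from confusion counts."""
    if counts.total == 0:
        raise ValueError("no pixels were evaluated")
    return TissueMetrics(
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.fp + counts.tn),
        accuracy=_ratio(counts.tp + counts.tn, counts.total),
    )


def evaluate_tissues(tissue_map, truth, eval_mask=None,
                     tissues=BRAIN_TISSUES) -> dict:
    """One-vs-rest metrics for each tissue code, plus macro-averages.

    Returns ``{tissue_name: TissueMetrics, ..., "macro": TissueMetrics}``;
    macro-averages ignore undefined (None) entries.
    """
    pred = np.asarray(tissue_map)
    ref = np.asarray(truth)
    out = {}
    for code in tissues:
        counts = confusion_counts(pred == code, ref == code, eval_mask)
        out[TISSUE_NAMES[code]] = evaluate(counts)

    def macro(attr):
        vals = [getattr(m, attr) for m in out.values()
                if getattr(m, attr) is not None]
        return sum(vals) / len(vals) if vals else None

    out["macro"] = TissueMetrics(sensitivity=macro("sensitivity"),
                                 specificity=macro("specificity"),
                                 accuracy=macro("accuracy"))
    return out
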