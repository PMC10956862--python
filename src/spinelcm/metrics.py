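"""Segmentation evaluation: confusion counts, accuracy/sensitivity/
specificity, and the Dice overlap score.

All values are kept as fractions in [0, 1] internally; percent formatting
belongs to the reporting layer.  0/0 cases (e.g. sensitivity with no
positive truth pixels) return NaN as an explicit undefined marker rather
than a silent zero, so averages over batches are not corrupted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "SegScores", "confusion_counts", "segmentation_scores", "dice_score"]

UNDEFINED = float("nan")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class SegScores:
    """Fractions in [0, 1]; NaN marks an undefined (0/0) metric."""

    accuracy: float
    sensitivity: float
    specificity: float
    dice: float

    def as_percent(self) -> dict:
        return {
            "accuracy_pct": 100.0 * self.accuracy,
            "sensitivity_pct": 100.0 * self.sensitivity,
            "specificity_pct": 100.0 * self.specificity,
            "dice": self.dice,
        }


def _as_mask(m) -> np.ndarray:
    m = getattr(m, "mask", m)
    return np.asarray(m, dtype=bool)


def confusion_counts(pred, truth, roi=None) -> ConfusionCounts:
    """Pixelwise confusion tally; foreground is the positive class.

    ``roi`` (an object with a ``crop`` method, e.g. ROIBox) restricts the
    count to a sub-window of both masks.
    """
    p = _as_mask(pred)
    t = _as_mask(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if roi is not None:
        p = roi.crop(p)
        t = roi.crop(t)
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


def segmentation_scores(counts: ConfusionCounts) -> SegScores:
    """accuracy=(tp+tn)/total, sensitivity=tp/(tp+fn),
    specificity=tn/(tn+fp), dice=2tp/(2tp+fp+fn)."""
    if counts.total <= 0:
        raise ValueError("empty confusion counts")
    return SegScores(
        accuracy=(counts.tp + counts.tn) / counts.total,
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        dice=_ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn),
    )


def dice_score(pred, truth) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two binary masks."""
    return segmentation_scores(confusion_counts(pred, truth)).dice
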