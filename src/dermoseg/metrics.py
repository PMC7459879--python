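"""Pixelwise segmentation evaluation: confusion counts and overlap metrics.

Foreground pixels are lesion.  Sensitivity, specificity, Dice, Jaccard
and accuracy follow the usual confusion-table formulas; mask IOU equals
the Jaccard index by the set identity |P∩T| / |P∪T|.  Metrics with a
zero denominator are reported as ``None`` (explicitly undefined), never
silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import validate_mask

__all__ = ["ConfusionCounts", "SegmentationScores", "confusion", "metrics", "mask_iou"]


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
class SegmentationScores:
    """Sen/Spe/Dic/Jac/Acc as fractions; None where undefined."""

    sen: float | None
    spe: float | None
    dic: float | None
    jac: float | None
    acc: float | None


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Per-pixel confusion tabulation of two congruent boolean masks."""
    pred = validate_mask(pred)
    truth = validate_mask(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(c: ConfusionCounts) -> SegmentationScores:
    """Sen = TP/(TP+FN), Spe = TN/(TN+FP), Dic = 2TP/(2TP+FP+FN),
    Jac = TP/(TP+FN+FP), Acc = (TP+TN)/total."""
    return SegmentationScores(
        sen=_ratio(c.tp, c.tp + c.fn),
        spe=_ratio(c.tn, c.tn + c.fp),
        dic=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        jac=_ratio(c.tp, c.tp + c.fn + c.fp),
        acc=_ratio(c.tp + c.tn, c.total),
    )


def mask_iou(pred: np.ndarray, truth: np.ndarray) -> float | None:
    """|pred ∩ truth| / |pred ∪ truth|; None when both masks are empty."""
    pred = validate_mask(pred)
    truth = validate_mask(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    union = int(np.count_nonzero(pred | truth))
    if union == 0:
        return None
    return int(np.count_nonzero(pred & truth)) / union
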