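"""Detector-side geometry: grid cells, bounding boxes, confidence, IOU.

A single-shot detector divides the image into an S x S grid; each cell
predicts B boxes of 5 components (x, y, w, h, confidence) plus C class
probabilities, so the output tensor is S x S x (B*5 + C).  Only this
arithmetic plus an untrained intensity-based ROI proposer is provided
here — no network, no weights — so the pipeline runs end to end with
either a ground-truth box file or the proposer as the ROI stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .preprocess import to_grayscale
from .raster import validate_image

__all__ = [
    "BoundingBox",
    "DetectionGrid",
    "box_iou",
    "confidence_score",
    "output_tensor_shape",
    "accept_detection",
    "propose_roi",
]


@dataclass(frozen=True)
class BoundingBox:
    """Center-format box: (x, y) center in px, width/height in px."""

    x: float
    y: float
    w: float
    h: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box width and height must be positive")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")

    def corners(self) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) corner form."""
        return (
            self.x - self.w / 2.0,
            self.y - self.h / 2.0,
            self.x + self.w / 2.0,
            self.y + self.h / 2.0,
        )

    @staticmethod
    def from_corners(x0: float, y0: float, x1: float, y1: float, confidence: float = 1.0) -> "BoundingBox":
        return BoundingBox(
            x=(x0 + x1) / 2.0, y=(y0 + y1) / 2.0, w=x1 - x0, h=y1 - y0,
            confidence=confidence,
        )


@dataclass(frozen=True)
class DetectionGrid:
    """S cells per side, B boxes per cell, C classes."""

    S: int
    B: int
    C: int

    def __post_init__(self) -> None:
        if self.S < 1 or self.B < 1 or self.C < 1:
            raise ValueError("S, B and C must all be >= 1")


def box_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection area over union area; 0 for disjoint boxes."""
    ax0, ay0, ax1, ay1 = a.corners()
    bx0, by0, bx1, by1 = b.corners()
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a.w * a.h + b.w * b.h - inter
    return inter / union


def confidence_score(object_present: bool, iou: float) -> float:
    """Pr(object) x IOU: zero when no object is present, else the IOU."""
    if not (0.0 <= iou <= 1.0):
        raise ValueError(f"iou must be in [0, 1], got {iou}")
    return iou if object_present else 0.0


def output_tensor_shape(g: DetectionGrid) -> tuple[int, int, int]:
    """Output tensor shape S x S x (B*5 + C)."""
    return (g.S, g.S, g.B * 5 + g.C)


def accept_detection(
    pred: BoundingBox, truth: BoundingBox, threshold: float = 0.80
) -> bool:
    """Accept a detection only when IOU is strictly greater than threshold."""
    return box_iou(pred, truth) > threshold


def propose_roi(gray: np.ndarray, margin: float = 0.0) -> BoundingBox:
    """Untrained ROI proposer: box of the largest dark component.

    The grayscale image is thresholded (Otsu); the dark side is taken
    as foreground, its largest connected component's bounding box is
    expanded by ``margin`` (fraction of box size) and clipped to the
    image.  Confidence is the component's darkness contrast against
    the rest of the image, normalized to [0, 1].  A featureless image
    yields the whole-image box with confidence 0.
    """
    gray = to_grayscale(validate_image(gray))
    h, w = gray.shape
    whole = BoundingBox(x=w / 2.0, y=h / 2.0, w=float(w), h=float(h), confidence=0.0)
    if gray.min() == gray.max():
        return whole
    thr = threshold_otsu(gray)
    dark = gray <= thr
    labels = measure.label(dark, connectivity=2)
    if labels.max() == 0:
        return whole
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    comp = labels == int(sizes.argmax())
    rows, cols = np.nonzero(comp)
    y0, y1 = rows.min(), rows.max() + 1
    x0, x1 = cols.min(), cols.max() + 1
    mx = margin * (x1 - x0)
    my = margin * (y1 - y0)
    x0 = max(0.0, x0 - mx)
    x1 = min(float(w), x1 + mx)
    y0 = max(0.0, y0 - my)
    y1 = min(float(h), y1 + my)
    contrast = float(gray[~comp].mean() - gray[comp].mean()) / 255.0
    conf = min(1.0, max(0.0, contrast))
    return BoundingBox.from_corners(x0, y0, x1, y1, confidence=conf)
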