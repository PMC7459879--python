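"""End-to-end lesion analysis: preprocess -> ROI -> two-pass segmentation
-> boundary tracing -> ABCD features -> optional evaluation.

Given one image (and optional ground truth), the pipeline

1. removes hair and equalizes contrast,
2. proposes (or accepts) a region of interest,
3. runs the two-pass block/fuzzy segmenter inside the ROI,
4. fills holes in the final mask and extracts ABCD features — colors
   are classified on the hair-repaired, *pre-equalization* RGB so the
   value channel still matches the reference HSV boxes,
5. scores the mask against a truth mask when one is given.

Deterministic: the same image and config always produce the same report.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .config import PipelineConfig
from .detect import BoundingBox, propose_roi
from .features import CameraModel, LesionFeatures, extract_features
from .graphseg import SegmentationConfig, SegmentationOutcome, segment
from .metrics import SegmentationScores, confusion, mask_iou, metrics
from .preprocess import detect_hair, equalize_histogram, remove_hair, to_grayscale
from .raster import load_image, validate_image, validate_mask

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    mask: np.ndarray                     # final lesion mask (full frame)
    features: LesionFeatures
    segmentation: SegmentationOutcome
    roi: BoundingBox
    scores: SegmentationScores | None
    iou: float | None
    report: dict = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def _resize(img: np.ndarray, size: int) -> np.ndarray:
    from PIL import Image

    mode = Image.fromarray(img)
    return np.asarray(mode.resize((size, size), Image.BILINEAR), dtype=np.uint8)


def _crop_box(
    box: BoundingBox, shape: tuple[int, int], align: int = 4
) -> tuple[int, int, int, int]:
    """Integer crop of ``box`` clipped to the image and aligned outward to
    the block grid, so partial (zero-padded) blocks only occur at the
    image's own right/bottom edge."""
    x0, y0, x1, y1 = box.corners()
    r0 = max(0, int(np.floor(y0)))
    c0 = max(0, int(np.floor(x0)))
    r1 = min(shape[0], int(np.ceil(y1)))
    c1 = min(shape[1], int(np.ceil(x1)))
    if r1 <= r0 or c1 <= c0:
        raise ValueError("ROI box does not intersect the image")
    r0, c0 = (r0 // align) * align, (c0 // align) * align
    r1 = min(shape[0], -(-r1 // align) * align)
    c1 = min(shape[1], -(-c1 // align) * align)
    return r0, c0, r1, c1


def run_pipeline(
    image,
    config: PipelineConfig | None = None,
    truth_mask: np.ndarray | None = None,
    truth_box: BoundingBox | None = None,
) -> PipelineResult:
    """Run the whole analysis on one image (path or uint8 array)."""
    cfg = config or PipelineConfig()
    log: list[str] = []

    def stage(name: str, t0: float, detail: str = "") -> None:
        log.append(f"{name}: {detail} ({time.perf_counter() - t0:.3f}s)")

    img = load_image(image) if isinstance(image, (str, bytes)) or hasattr(image, "__fspath__") else validate_image(image)
    if cfg.resize is not None:
        img = _resize(img, cfg.resize)
    if truth_mask is not None:
        truth_mask = validate_mask(truth_mask, like=img)

    # --- preprocessing -----------------------------------------------------
    t0 = time.perf_counter()
    if cfg.hair_removal:
        hair = detect_hair(
            img,
            struct_len=cfg.hair_struct_len,
            thickness_max=cfg.hair_thickness_max,
            length_min=cfg.hair_length_min,
        )
        clean = (
            remove_hair(img, hair, median_window=cfg.hair_median_window)
            if hair.any()
            else img
        )
        stage("hair_removal", t0, f"{int(hair.sum())} px flagged")
    else:
        clean = img
        stage("hair_removal", t0, "skipped")

    t0 = time.perf_counter()
    enhanced = equalize_histogram(clean) if cfg.equalize else clean
    stage("equalize", t0, "on" if cfg.equalize else "skipped")

    # --- ROI ---------------------------------------------------------------
    t0 = time.perf_counter()
    # ROI proposal and segmentation share one grayscale; equalization is
    # kept out of it by default (it amplifies background noise)
    gray = to_grayscale(enhanced if cfg.segment_on_equalized else clean)
    if truth_box is not None:
        roi = truth_box
        stage("roi", t0, "ground-truth box")
    elif cfg.use_roi:
        roi = propose_roi(gray, margin=cfg.roi_margin)
        stage("roi", t0, f"proposed conf={roi.confidence:.2f}")
    else:
        h, w = gray.shape
        roi = BoundingBox(x=w / 2, y=h / 2, w=float(w), h=float(h), confidence=0.0)
        stage("roi", t0, "whole image")

    # --- segmentation ------------------------------------------------------
    t0 = time.perf_counter()
    r0, c0, r1, c1 = _crop_box(roi, gray.shape, align=cfg.block_size)
    seg_cfg = SegmentationConfig(threshold=cfg.threshold, block_size=cfg.block_size)
    outcome = segment(gray[r0:r1, c0:c1], seg_cfg, single_pass=cfg.single_pass)
    full = np.zeros(gray.shape, dtype=bool)
    full[r0:r1, c0:c1] = outcome.mask2.pixels
    mask = ndi.binary_fill_holes(full)
    d_txt = "single pass" if outcome.D is None else f"D={outcome.D:.2f}"
    stage("segment", t0, f"T={outcome.T:.2f} {d_txt}")
    if not mask.any():
        raise ValueError("segmentation selected no lesion pixels (no-lesion)")
    if mask.mean() > 0.9:
        # a featureless frame selects every block (W == T everywhere):
        # "everything is lesion" is no lesion at all
        raise ValueError("segmentation covers the whole frame (no-lesion)")

    # --- features ----------------------------------------------------------
    t0 = time.perf_counter()
    cam = None
    if cfg.focal_mm is not None and cfg.distance_mm is not None:
        cam = CameraModel(f=cfg.focal_mm, u=cfg.distance_mm, pixel_pitch=cfg.pixel_pitch)
    feats = extract_features(
        clean if clean.ndim == 3 else None,
        mask,
        angle_step=cfg.angle_step,
        tol_rel=cfg.asym_tol_rel,
        cam=cam,
        color_tol=(cfg.color_tol_h, cfg.color_tol_s, cfg.color_tol_v),
        min_color_pixels=cfg.min_color_pixels,
    )
    stage("features", t0, f"d={feats.diameter_px:.1f}px")

    # --- evaluation --------------------------------------------------------
    scores = None
    iou = None
    if truth_mask is not None:
        t0 = time.perf_counter()
        scores = metrics(confusion(mask, truth_mask))
        iou = mask_iou(mask, truth_mask)
        stage("evaluate", t0, f"jac={scores.jac:.3f}" if scores.jac is not None else "")

    report = {
        "roi": {"x": roi.x, "y": roi.y, "w": roi.w, "h": roi.h,
                "confidence": roi.confidence},
        "thresholds": {"T": outcome.T, "D": outcome.D},
        "center": {"x": feats.center.x, "y": feats.center.y},
        "probe_center": {"x": feats.probe_center.x, "y": feats.probe_center.y},
        "asymmetric": feats.asymmetric,
        "asymmetry_fraction": feats.asymmetry_fraction,
        "colors": sorted(feats.colors),
        "diameter_px": feats.diameter_px,
        "area_px": feats.area_px,
        "diameter_mm": feats.diameter_mm,
        "area_mm2": feats.area_mm2,
        "units": feats.units,
    }
    if scores is not None:
        report["scores"] = {
            "sen": scores.sen, "spe": scores.spe, "dic": scores.dic,
            "jac": scores.jac, "acc": scores.acc, "iou": iou,
        }
    return PipelineResult(
        mask=mask, features=feats, segmentation=outcome, roi=roi,
        scores=scores, iou=iou, report=report, log=log,
    )
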