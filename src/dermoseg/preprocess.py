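"""Dermoscopic image preprocessing: hair removal and contrast enhancement.

The hair-removal stage follows the classic razor recipe: a grey
morphological closing with linear structuring elements at several
orientations highlights thin dark structures; the closing residual is
thresholded adaptively, candidate components are vetted by length and
thickness so that wide dark blobs (the lesion itself) are never touched,
flagged pixels are replaced by bilinear interpolation from the nearest
clean pixels, and the repaired region is smoothed with a median filter.

Histogram equalization uses the standard cumulative-distribution
remapping.  On color input only the luminance is equalized and chroma is
preserved by per-pixel scaling, so downstream hue/saturation color
classification is not corrupted.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.morphology import closing

from .raster import validate_image, validate_mask

__all__ = ["to_grayscale", "detect_hair", "remove_hair", "equalize_histogram"]

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Luma grayscale conversion; single-channel input is returned unchanged."""
    img = validate_image(img)
    if img.ndim == 2:
        return img
    gray = img.astype(np.float64) @ _LUMA
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def _line_footprints(length: int) -> list[np.ndarray]:
    """Linear structuring elements at 0, 45, 90 and 135 degrees."""
    horiz = np.ones((1, length), dtype=bool)
    vert = np.ones((length, 1), dtype=bool)
    diag = np.eye(length, dtype=bool)
    return [horiz, vert, diag, diag[::-1]]


def detect_hair(
    img: np.ndarray,
    struct_len: int = 9,
    thickness_max: float = 5.0,
    length_min: float = 15.0,
) -> np.ndarray:
    """Locate thin dark hair strokes; returns a boolean mask.

    Pixels whose multi-orientation closing residual exceeds an adaptive
    contrast threshold (mean + 2 std of the residual image) form
    candidate components; a component is accepted as hair only when its
    major-axis length is at least ``length_min`` and its mean width
    (area / length) is at most ``thickness_max`` pixels.
    """
    if struct_len < 3:
        raise ValueError(f"struct_len must be >= 3, got {struct_len}")
    gray = to_grayscale(img).astype(np.float64)
    closed = gray
    for fp in _line_footprints(struct_len):
        closed = np.maximum(closed, closing(gray, fp))
    residual = closed - gray  # positive where a thin dark structure was filled
    thr = residual.mean() + 2.0 * residual.std()
    candidates = residual > thr

    out = np.zeros(gray.shape, dtype=bool)
    labels = measure.label(candidates, connectivity=2)
    for region in measure.regionprops(labels):
        length = region.axis_major_length
        if length < length_min:
            continue
        mean_width = region.area / max(length, 1.0)
        if mean_width > thickness_max:
            continue
        out[labels == region.label] = True
    return out


def _interp_masked_1d(values: np.ndarray, masked: np.ndarray) -> np.ndarray | None:
    """Linear interpolation across masked runs of a single line.

    Returns None when every sample of the line is masked.
    """
    good = ~masked
    if not good.any():
        return None
    idx = np.arange(values.size)
    filled = values.astype(np.float64).copy()
    filled[masked] = np.interp(idx[masked], idx[good], values[good])
    return filled


def remove_hair(
    img: np.ndarray, mask: np.ndarray, median_window: int = 5
) -> np.ndarray:
    """Replace masked pixels by bilinear interpolation, then median-smooth.

    Each masked pixel gets the average of the horizontal and vertical
    linear interpolants from its nearest unmasked neighbors; a median
    filter of ``median_window`` is then applied inside the dilated mask
    only.  Pixels outside that region are returned bit-identical.
    """
    img = validate_image(img)
    mask = validate_mask(mask, like=img)
    if mask.all():
        raise ValueError("mask covers the whole image; nothing to interpolate from")
    if not mask.any():
        return img.copy()

    channels = img[..., None] if img.ndim == 2 else img
    out = channels.astype(np.float64).copy()
    for c in range(out.shape[2]):
        plane = out[:, :, c]
        horiz = np.empty_like(plane)
        horiz_ok = np.zeros(plane.shape, dtype=bool)
        for r in range(plane.shape[0]):
            filled = _interp_masked_1d(plane[r], mask[r])
            if filled is not None:
                horiz[r] = filled
                horiz_ok[r] = True
        vert = np.empty_like(plane)
        vert_ok = np.zeros(plane.shape, dtype=bool)
        for col in range(plane.shape[1]):
            filled = _interp_masked_1d(plane[:, col], mask[:, col])
            if filled is not None:
                vert[:, col] = filled
                vert_ok[:, col] = True
        both = horiz_ok & vert_ok
        plane[mask & both] = 0.5 * (horiz + vert)[mask & both]
        plane[mask & horiz_ok & ~vert_ok] = horiz[mask & horiz_ok & ~vert_ok]
        plane[mask & vert_ok & ~horiz_ok] = vert[mask & vert_ok & ~horiz_ok]
        # pixels with fully-masked row and column: nearest clean pixel
        orphan = mask & ~horiz_ok & ~vert_ok
        if orphan.any():
            _, (ir, ic) = ndi.distance_transform_edt(mask, return_indices=True)
            plane[orphan] = plane[ir[orphan], ic[orphan]]

    result = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    region = ndi.binary_dilation(mask, iterations=max(1, median_window // 2))
    for c in range(result.shape[2]):
        med = ndi.median_filter(result[:, :, c], size=median_window)
        result[:, :, c][region] = med[region]
    return result[:, :, 0] if img.ndim == 2 else result


def _equalize_channel(gray: np.ndarray) -> np.ndarray:
    """CDF remap of one uint8 channel; constant input is returned as-is."""
    hist = np.bincount(gray.ravel(), minlength=256)
    nonzero = np.nonzero(hist)[0]
    if nonzero.size <= 1:
        return gray.copy()
    cdf = np.cumsum(hist)
    cdf_min = cdf[nonzero[0]]
    total = gray.size
    lut = np.rint((cdf - cdf_min) / (total - cdf_min) * 255.0)
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    return lut[gray]


def equalize_histogram(img: np.ndarray) -> np.ndarray:
    """Histogram equalization; monotone remapping preserves intensity order.

    RGB images are equalized on the luminance channel with chroma kept by
    scaling each pixel's channels by the luminance ratio.
    """
    img = validate_image(img)
    if img.ndim == 2:
        return _equalize_channel(img)
    luma = to_grayscale(img)
    eq = _equalize_channel(luma)
    ratio = np.where(luma > 0, eq / np.maximum(luma, 1), 0.0)
    out = img.astype(np.float64) * ratio[..., None]
    out[luma == 0] = eq[luma == 0, None]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
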