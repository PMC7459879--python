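"""ABCD feature extraction from a segmented lesion mask.

Implements the clinical ABCD quantities on a traced lesion boundary:

* **A**symmetry / **B**order — a center point is probed by straight
  lines ``y = tan(a)(x - x0) + y0`` rotated through [0, 180); the two
  boundary hits of each line give radii ``dk1, dk2`` whose inequality
  "in maximum cases" (majority of probe angles) flags an asymmetric,
  irregular lesion.
* **C**olor — lesion pixels are mapped to HSV and matched against six
  reference color boxes (light brown, dark brown, tan black, blue gray,
  red, white); a 4-neighbour "plus" operation suppresses uniform
  interior pixels so clusters are reported by their salient pixels.
* **D**iameter — the maximum pairwise distance between boundary pixels,
  plus the shoelace polygon area, both optionally rescaled to
  millimetres through a thin-lens magnification model
  ``L = d * (u + f) / f``.

The center-point machinery includes the iterated-midpoint "resultant"
construction: c1 = p1, c_k = (c_{k-1} + p_k)/2, whose closed form
weights the i-th point by 2^(i-2) / 2^(n-1).  The result is dominated
by the tail of the point ordering, so the plain mask centroid is also
provided (and is what the pipeline probes from).

Coordinates are (x = column, y = row), 0-based, y increasing downward;
angles are measured in degrees from the horizontal axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import color as skcolor
from skimage import measure

from .raster import validate_image, validate_mask

__all__ = [
    "Contour",
    "CenterPoint",
    "AngleProbe",
    "ColorClassMap",
    "CameraModel",
    "LesionFeatures",
    "COLOR_LEGEND",
    "DEFAULT_HSV_BOXES",
    "extract_contour",
    "mask_centroid",
    "mask_points_raster",
    "center_resultant",
    "probe_line_slope",
    "probe_intersections",
    "assess_asymmetry",
    "classify_colors",
    "lesion_diameter",
    "signed_area",
    "polygon_area",
    "physical_scale",
    "extract_features",
]


@dataclass(frozen=True)
class Contour:
    """Ordered closed boundary; ``points`` is (n, 2) float, columns (x, y)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=np.float64)
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
            raise ValueError(f"contour needs >= 3 (x, y) points, got shape {p.shape}")
        object.__setattr__(self, "points", p)

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class CenterPoint:
    x: float
    y: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=np.float64)


@dataclass(frozen=True)
class AngleProbe:
    """One rotated line through the center and its two boundary hits."""

    angle: float
    slope: float | None  # None marks the vertical (90 degree) probe
    hit1: tuple[float, float]
    hit2: tuple[float, float]
    dk1: float
    dk2: float


# class label -> clinical color name (0 = unclassified)
COLOR_LEGEND = {
    1: "light brown",
    2: "dark brown",
    3: "tan black",
    4: "blue gray",
    5: "red",
    6: "white",
}

# Inclusive HSV boxes per class, H in degrees [0, 360), S and V in percent.
# Each box is stated by two corner triples; per-channel min/max taken.
DEFAULT_HSV_BOXES = {
    1: ((30, 62, 77), (30, 68, 57)),
    2: ((30, 67, 51), (30, 67, 28)),
    3: ((30, 67, 22), (30, 67, 11)),
    4: ((60, 2, 17), (30, 0, 10)),
    5: ((0, 100, 46), (0, 87, 70)),
    6: ((0, 0, 94), (0, 0, 98)),
}


@dataclass
class ColorClassMap:
    """Per-pixel color class labels and the salient (kept) pixels.

    ``labels``: raw per-pixel class (0 = unclassified / outside mask);
    ``kept``: pixels surviving the border-line / plus-operation rule;
    ``counts``: kept-pixel count per class label.
    """

    labels: np.ndarray
    kept: np.ndarray
    counts: dict[int, int]
    legend: dict[int, str] = field(default_factory=lambda: dict(COLOR_LEGEND))


@dataclass(frozen=True)
class CameraModel:
    """Thin-lens capture geometry.

    f: focal length (mm); u: object distance (mm); pixel_pitch: mm per
    pixel on the image plane, or None when unknown (results then stay
    in pixel 'units').
    """

    f: float
    u: float
    pixel_pitch: float | None = None

    def __post_init__(self) -> None:
        if self.f <= 0 or self.u <= 0:
            raise ValueError("focal length and object distance must be positive")
        if self.pixel_pitch is not None and self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive when given")


@dataclass
class LesionFeatures:
    """Full ABCD report for one lesion."""

    center: CenterPoint              # resultant-method center
    probe_center: CenterPoint        # centroid used for asymmetry probing
    asymmetric: bool
    asymmetry_fraction: float
    colors: set[int]
    diameter_px: float
    diameter_endpoints: tuple[tuple[float, float], tuple[float, float]]
    area_px: float
    diameter_mm: float | None = None
    area_mm2: float | None = None
    units: str = "units"


# ---------------------------------------------------------------------------
# boundary tracing

# Moore neighborhood in clockwise order, as (dr, dc), starting at West
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def _moore_step(
    padded: np.ndarray, current: tuple[int, int], backtrack: tuple[int, int]
) -> tuple[tuple[int, int] | None, tuple[int, int]]:
    """One step of Moore tracing: scan the 8-ring clockwise from the
    backtrack pixel; returns (next foreground pixel or None, its backtrack)."""
    db = (backtrack[0] - current[0], backtrack[1] - current[1])
    k0 = _MOORE.index(db)
    new_backtrack = backtrack
    for step in range(1, 9):
        dr, dc = _MOORE[(k0 + step) % 8]
        cand = (current[0] + dr, current[1] + dc)
        if padded[cand]:
            return cand, new_backtrack
        new_backtrack = cand
    return None, backtrack


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        raise ValueError("empty mask: no lesion to trace")
    if labels.max() > 1:
        warnings.warn(
            f"mask has {labels.max()} components; tracing the largest",
            stacklevel=3,
        )
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        keep = int(sizes.argmax())  # argmax ties -> first raster occurrence
        return labels == keep
    return labels == 1


def extract_contour(mask: np.ndarray) -> Contour:
    """Trace the ordered outer boundary of the largest mask component.

    Moore-neighbor tracing with Jacob's stopping criterion; consecutive
    points are 8-connected integer pixel centers.  Orientation is
    normalized so the signed shoelace sum is positive.
    """
    mask = validate_mask(mask)
    comp = _largest_component(mask)
    padded = np.pad(comp, 1)
    rs, cs = np.nonzero(padded)
    start = (int(rs[0]), int(cs[0]))  # topmost, then leftmost

    boundary: list[tuple[int, int]] = [start]
    # backtrack: the background neighbor we entered from (West of start)
    backtrack = (start[0], start[1] - 1)
    current = start
    max_steps = 4 * int(padded.sum()) + 8
    for _ in range(max_steps):
        nxt, new_backtrack = _moore_step(padded, current, backtrack)
        if nxt is None:  # isolated single pixel
            break
        if nxt == start:
            # stop when the walk would repeat itself from the start pixel
            follow, _ = _moore_step(padded, start, new_backtrack)
            if len(boundary) == 1 or follow is None or follow == boundary[1]:
                break
        boundary.append(nxt)
        current, backtrack = nxt, new_backtrack

    pts = np.array(
        [(c - 1, r - 1) for r, c in boundary], dtype=np.float64
    )  # back to (x, y) in unpadded coords
    if pts.shape[0] < 3:
        raise ValueError("lesion too small to form a closed boundary")
    if signed_area(pts) < 0:
        pts = pts[::-1]
    return Contour(points=pts)


# ---------------------------------------------------------------------------
# center points


def mask_points_raster(mask: np.ndarray) -> np.ndarray:
    """All foreground pixel coordinates (x, y) in raster order."""
    rows, cols = np.nonzero(validate_mask(mask))
    return np.column_stack([cols, rows]).astype(np.float64)


def mask_centroid(mask: np.ndarray) -> CenterPoint:
    pts = mask_points_raster(mask)
    if pts.shape[0] == 0:
        raise ValueError("empty mask has no centroid")
    return CenterPoint(float(pts[:, 0].mean()), float(pts[:, 1].mean()))


def center_resultant(points: np.ndarray) -> CenterPoint:
    """Iterated-midpoint resultant of an ordered point sequence.

    c1 = p1; c_k = (c_{k-1} + p_k)/2.  Equals the closed form
    (p1 + sum_{i>=2} 2^(i-2) p_i) / 2^(n-1), computed iteratively for
    numerical stability.  Ordering matters: later points dominate.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ValueError("need an (n, 2) array with n >= 1")
    c = pts[0].copy()
    for p in pts[1:]:
        c = (c + p) / 2.0
    return CenterPoint(float(c[0]), float(c[1]))


# ---------------------------------------------------------------------------
# asymmetry / border probes


def probe_line_slope(angle: float) -> float:
    """Gradient m = tan(angle) of a probe line; angle in degrees.

    The vertical probe (90 degrees) has no finite slope and is handled
    as a special case by :func:`probe_intersections`.
    """
    if not (0.0 <= angle < 180.0):
        raise ValueError(f"angle must be in [0, 180), got {angle}")
    if angle == 90.0:
        raise ValueError("vertical probe has undefined slope")
    return math.tan(math.radians(angle))


def probe_intersections(
    contour: Contour, center: CenterPoint, angle: float, tol: float = 1.5
) -> AngleProbe:
    """Boundary hits of the line through ``center`` at ``angle`` degrees.

    On each side of the center the contour point nearest to the ideal
    line (perpendicular distance <= ``tol``) is taken as the hit; the
    radii dk1, dk2 are the Euclidean distances from the center to the
    hits.  Raises if either side has no boundary point within ``tol``.
    """
    theta = math.radians(angle)
    u = np.array([math.cos(theta), math.sin(theta)])
    nrm = np.array([-math.sin(theta), math.cos(theta)])
    rel = contour.points - center.as_array()
    t = rel @ u
    perp = np.abs(rel @ nrm)

    hits = []
    for side in (1.0, -1.0):
        sel = np.nonzero((t * side > 0) & (perp <= tol))[0]
        if sel.size == 0:
            raise ValueError(
                f"no boundary point within {tol} px of the {angle} degree probe"
            )
        # nearest to the line; ties broken on the farther (outermost) point
        order = np.lexsort((-np.abs(t[sel]), perp[sel]))
        hits.append(int(sel[order[0]]))

    p1, p2 = contour.points[hits[0]], contour.points[hits[1]]
    dk1 = float(np.hypot(*(p1 - center.as_array())))
    dk2 = float(np.hypot(*(p2 - center.as_array())))
    slope = None if angle == 90.0 else math.tan(theta)
    return AngleProbe(
        angle=angle,
        slope=slope,
        hit1=(float(p1[0]), float(p1[1])),
        hit2=(float(p2[0]), float(p2[1])),
        dk1=dk1,
        dk2=dk2,
    )


def assess_asymmetry(
    contour: Contour,
    center: CenterPoint,
    angle_step: float = 5.0,
    tol_rel: float = 0.1,
    tol_px: float = 1.5,
) -> tuple[bool, float, list[AngleProbe]]:
    """Majority vote over rotated probes: asymmetric when most radii differ.

    A probe is unequal when |dk1 - dk2| > tol_rel * max(dk1, dk2); the
    lesion is called asymmetric when more than half the probes are
    unequal ("in maximum cases").
    """
    if angle_step <= 0 or (180.0 / angle_step) != int(180.0 / angle_step):
        raise ValueError(f"angle_step must divide 180, got {angle_step}")
    probes = []
    unequal = 0
    n = int(180.0 / angle_step)
    for k in range(n):
        probe = probe_intersections(contour, center, k * angle_step, tol=tol_px)
        probes.append(probe)
        if abs(probe.dk1 - probe.dk2) > tol_rel * max(probe.dk1, probe.dk2):
            unequal += 1
    fraction = unequal / n
    return fraction > 0.5, fraction, probes


# ---------------------------------------------------------------------------
# color classification


def _hsv_boxes(boxes, tol: tuple[float, float, float]) -> dict[int, np.ndarray]:
    """Resolve corner-pair boxes to per-channel [min, max] with expansion."""
    resolved = {}
    for label, (a, b) in boxes.items():
        lo = np.minimum(a, b).astype(np.float64) - np.asarray(tol)
        hi = np.maximum(a, b).astype(np.float64) + np.asarray(tol)
        resolved[label] = np.stack([lo, hi])
    return resolved


def classify_colors(
    rgb: np.ndarray,
    mask: np.ndarray,
    boxes=None,
    tol: tuple[float, float, float] = (1.0, 1.0, 1.0),
    min_pixels: int = 20,
    smooth: int | None = 5,
) -> tuple[ColorClassMap, set[int]]:
    """Assign lesion pixels to the six reference color classes.

    Each masked pixel is converted to HSV (H in degrees, S and V in
    percent) and matched against the inclusive class boxes (expanded by
    ``tol`` per channel to absorb 8-bit quantization).  A ``smooth`` x
    ``smooth`` median prefilter suppresses sensor noise before the
    conversion — at dark values even small RGB noise swings hue by tens
    of degrees; background pixels are blanked first so nothing outside
    the mask can influence a label.  The working label grid is padded
    by one zero pixel; labeled pixels on a cluster border line are
    always kept, interior pixels are suppressed when their label does
    not exceed the mean of their 4-neighborhood (the "plus" operation).
    A class enters the reported color set when at least ``min_pixels``
    of its pixels survive.
    """
    rgb = validate_image(rgb)
    if rgb.ndim != 3:
        raise ValueError("classify_colors requires a 3-channel image")
    mask = validate_mask(mask, like=rgb)
    resolved = _hsv_boxes(boxes or DEFAULT_HSV_BOXES, tol)

    work = rgb.astype(np.float64)
    if smooth is not None and smooth > 1:
        from scipy import ndimage as ndi

        blanked = work.copy()
        blanked[~mask] = 0.0
        work = np.stack(
            [ndi.median_filter(blanked[..., c], size=smooth) for c in range(3)],
            axis=-1,
        )
    hsv = skcolor.rgb2hsv(work / 255.0)
    hsv = hsv * np.array([360.0, 100.0, 100.0])

    # hue is numerically meaningless for near-achromatic pixels (8-bit
    # quantization collapses it to 0), so S below this floor makes the
    # H constraint a wildcard
    s_achromatic = 5.0
    labels = np.zeros(mask.shape, dtype=np.int8)
    unassigned = mask.copy()
    for lab in sorted(resolved):
        (h0, s0, v0), (h1, s1, v1) = resolved[lab]
        h_ok = (hsv[..., 0] >= h0) & (hsv[..., 0] <= h1)
        if s1 <= s_achromatic:
            h_ok |= hsv[..., 1] < s_achromatic
        inside = (
            h_ok
            & (hsv[..., 1] >= s0) & (hsv[..., 1] <= s1)
            & (hsv[..., 2] >= v0) & (hsv[..., 2] <= v1)
        )
        hit = unassigned & inside
        labels[hit] = lab
        unassigned &= ~hit

    # plus operation on the zero-padded working grid
    f1 = np.pad(labels.astype(np.float64), 1)
    core = f1[1:-1, 1:-1]
    up, down = f1[:-2, 1:-1], f1[2:, 1:-1]
    left, right = f1[1:-1, :-2], f1[1:-1, 2:]
    neighbor_mean = (up + down + left + right) / 4.0
    border_line = (
        (up != core) | (down != core) | (left != core) | (right != core)
    )
    labeled = labels > 0
    kept = labeled & (border_line | (core > neighbor_mean))

    counts = {
        int(lab): int(np.count_nonzero(kept & (labels == lab)))
        for lab in np.unique(labels[labels > 0])
    }
    colors = {lab for lab, n in counts.items() if n >= min_pixels}
    return ColorClassMap(labels=labels, kept=kept, counts=counts), colors


# ---------------------------------------------------------------------------
# diameter, area, physical scaling


def lesion_diameter(points) -> tuple[float, tuple[tuple[float, float], tuple[float, float]]]:
    """Maximum pairwise Euclidean distance between boundary points.

    Complete all-pairs search; on ties the pair with the smallest
    indices wins.  Accepts a Contour or an (n, 2) point array.
    """
    pts = points.points if isinstance(points, Contour) else np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (x, y) points")
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    flat = int(np.argmax(d2))  # row-major argmax -> smallest (i, j) on ties
    i, j = divmod(flat, pts.shape[0])
    d = float(math.sqrt(d2[i, j]))
    return d, ((float(pts[i, 0]), float(pts[i, 1])), (float(pts[j, 0]), float(pts[j, 1])))


def signed_area(points) -> float:
    """Signed shoelace sum (before the absolute value)."""
    pts = points.points if isinstance(points, Contour) else np.asarray(points, float)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _self_intersects(pts: np.ndarray) -> bool:
    """Brute-force proper-crossing test for small polygons."""
    n = pts.shape[0]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    for i in range(n):
        a, b = pts[i], pts[(i + 1) % n]
        for j in range(i + 1, n):
            if abs(i - j) <= 1 or (i == 0 and j == n - 1):
                continue
            c, d = pts[j], pts[(j + 1) % n]
            if (
                cross(a, b, c) * cross(a, b, d) < 0
                and cross(c, d, a) * cross(c, d, b) < 0
            ):
                return True
    return False


def polygon_area(points) -> float:
    """Orientation-independent shoelace area of a simple closed polygon."""
    pts = points.points if isinstance(points, Contour) else np.asarray(points, float)
    if pts.shape[0] < 3:
        raise ValueError("polygon needs at least 3 vertices")
    if pts.shape[0] <= 64 and _self_intersects(pts):
        warnings.warn("polygon appears self-intersecting; area may be unreliable")
    return abs(signed_area(pts))


def physical_scale(
    d_px: float, area_px: float, cam: CameraModel
) -> tuple[float, float, str]:
    """Rescale pixel measurements to object-plane millimetres.

    L = (d_px * pitch) * (u + f) / f and A = (area_px * pitch^2) *
    ((u + f)/f)^2.  Without a pixel pitch the values are returned
    unscaled and flagged as 'units'.
    """
    mag = (cam.u + cam.f) / cam.f
    if cam.pixel_pitch is None:
        return float(d_px), float(area_px), "units"
    length = d_px * cam.pixel_pitch * mag
    area = area_px * cam.pixel_pitch**2 * mag**2
    return float(length), float(area), "mm"


# ---------------------------------------------------------------------------
# orchestration


def extract_features(
    rgb: np.ndarray | None,
    mask: np.ndarray,
    angle_step: float = 5.0,
    tol_rel: float = 0.1,
    cam: CameraModel | None = None,
    color_boxes=None,
    color_tol: tuple[float, float, float] = (1.0, 1.0, 1.0),
    min_color_pixels: int = 20,
) -> LesionFeatures:
    """Full ABCD report for the largest lesion component of ``mask``.

    The resultant center is computed from all mask pixels in raster
    order (and reported); asymmetry probing uses the mask centroid,
    whose position does not depend on pixel ordering.  The reported
    area adds the half-boundary lattice correction (B/2 + 1) to the
    shoelace polygon area so it estimates the enclosed pixel count.
    """
    mask = validate_mask(mask)
    contour = extract_contour(mask)
    comp = _largest_component(mask)
    resultant = center_resultant(mask_points_raster(comp))
    centroid = mask_centroid(comp)
    asymmetric, fraction, _ = assess_asymmetry(
        contour, centroid, angle_step=angle_step, tol_rel=tol_rel
    )
    if rgb is not None and rgb.ndim == 3:
        _, colors = classify_colors(
            rgb, comp, boxes=color_boxes, tol=color_tol, min_pixels=min_color_pixels
        )
    else:
        colors = set()
    d_px, endpoints = lesion_diameter(contour)
    area_px = polygon_area(contour) + len(contour) / 2.0 + 1.0

    features = LesionFeatures(
        center=resultant,
        probe_center=centroid,
        asymmetric=asymmetric,
        asymmetry_fraction=fraction,
        colors=colors,
        diameter_px=d_px,
        diameter_endpoints=endpoints,
        area_px=area_px,
    )
    if cam is not None:
        length, area, units = physical_scale(d_px, area_px, cam)
        features.units = units
        if units == "mm":
            features.diameter_mm = length
            features.area_mm2 = area
    return features
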