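"""Seeded synthetic lesion phantoms with analytic ground truth.

A phantom is a skin-toned canvas with one darker lesion — a disk,
centered ellipse, notched disk (a wedge bite taken out) or irregular
radial blob r(theta) = R (1 + sum_k a_k cos(k theta + phi_k)) — whose
interior is painted from the reference HSV color classes, optionally
overlaid with thin dark hair strokes and clipped Gaussian pixel noise.

Ground truth (mask, contour, center, diameter, area, color set, box,
asymmetry verdict) is recorded alongside; diameter and area come from
the analytic shape, not the raster, so parameter-recovery tests measure
the pipeline's error, not the generator's.

Blob asymmetry truth is evaluated on the generating radial function:
the fraction of probe angles with |r(theta) - r(theta+pi)| exceeding
10% of the larger radius, the same majority rule the feature extractor
applies.  Suite shapes keep that fraction well away from the 0.5
decision boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage.draw import line as draw_line

from .detect import BoundingBox
from .features import (
    CenterPoint,
    Contour,
    DEFAULT_HSV_BOXES,
    extract_contour,
)

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "phantom_suite", "class_rgb"]

SKIN_RGB = (224, 172, 150)
HAIR_RGB = (28, 22, 18)


def class_rgb(label: int) -> tuple[int, int, int]:
    """Representative RGB (box-center HSV) of a reference color class."""
    (h0, s0, v0), (h1, s1, v1) = DEFAULT_HSV_BOXES[label]
    h = (min(h0, h1) + max(h0, h1)) / 2.0
    s = (min(s0, s1) + max(s0, s1)) / 2.0
    v = (min(v0, v1) + max(v0, v1)) / 2.0
    rgb = skcolor.hsv2rgb(np.array([[[h / 360.0, s / 100.0, v / 100.0]]]))
    return tuple(int(round(c * 255.0)) for c in rgb[0, 0])


@dataclass
class PhantomSpec:
    """Recipe for one phantom; deterministic given ``seed``."""

    seed: int
    canvas: tuple[int, int] = (160, 160)
    shape: str = "disk"  # disk | ellipse | notched-disk | blob
    radius: float = 32.0
    semi_axes: tuple[float, float] | None = None  # ellipse (a, b), a >= b
    notch_fraction: float = 0.0  # wedge bite, fraction of the full angle
    blob_harmonics: dict[int, float] = field(default_factory=dict)
    color_fractions: dict[int, float] = field(default_factory=lambda: {1: 1.0})
    skin_rgb: tuple[int, int, int] = SKIN_RGB
    hair_count: int = 0
    hair_width: int = 2
    noise_sd: float = 4.0
    center: tuple[float, float] | None = None  # (cx, cy); default canvas middle

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "ellipse", "notched-disk", "blob"):
            raise ValueError(f"unknown shape {self.shape!r}")
        total = sum(self.color_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"color fractions must sum to 1, got {total}")
        if not (0.0 <= self.notch_fraction < 0.5):
            raise ValueError("notch_fraction must be in [0, 0.5)")


@dataclass
class PhantomTruth:
    mask: np.ndarray
    contour: Contour
    center: CenterPoint
    diameter_px: float
    area_px: float
    colors: set[int]
    box: BoundingBox
    asymmetric: bool
    hair_mask: np.ndarray


def _radial_profile(spec: PhantomSpec, rng: np.random.Generator):
    """Radial function r(theta) and harmonic phases for blob shapes."""
    phases = {k: rng.uniform(0, 2 * math.pi) for k in sorted(spec.blob_harmonics)}

    def r_of(theta: np.ndarray) -> np.ndarray:
        out = np.full_like(theta, spec.radius, dtype=np.float64)
        for k, a in spec.blob_harmonics.items():
            out += spec.radius * a * np.cos(k * theta + phases[k])
        return out

    return r_of


def _analytic_blob_truth(r_of, tol_rel: float = 0.1):
    """(diameter, area, asymmetry fraction) of a radial blob by quadrature."""
    theta = np.linspace(0.0, 2 * math.pi, 4096, endpoint=False)
    r = r_of(theta)
    area = 0.5 * float(np.trapezoid(np.append(r, r[0]) ** 2, np.append(theta, 2 * math.pi)))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])[::4]
    diff = pts[:, None, :] - pts[None, :, :]
    diameter = float(np.sqrt((diff**2).sum(-1).max()))
    half = theta[: theta.size // 2]
    r1, r2 = r_of(half), r_of(half + math.pi)
    frac = float(np.mean(np.abs(r1 - r2) > tol_rel * np.maximum(r1, r2)))
    return diameter, area, frac


def _lesion_mask(spec: PhantomSpec, rng: np.random.Generator):
    """Raster mask + analytic (center, diameter, area, asymmetric)."""
    h, w = spec.canvas
    cx, cy = spec.center if spec.center is not None else ((w - 1) / 2.0, (h - 1) / 2.0)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    rr = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)

    center = CenterPoint(cx, cy)
    if spec.shape == "disk":
        mask = rr <= spec.radius
        truth = (2 * spec.radius, math.pi * spec.radius**2, False)
    elif spec.shape == "ellipse":
        a, b = spec.semi_axes if spec.semi_axes else (spec.radius, spec.radius / 1.5)
        mask = (dx / a) ** 2 + (dy / b) ** 2 <= 1.0
        truth = (2 * max(a, b), math.pi * a * b, False)
    elif spec.shape == "notched-disk":
        q = spec.notch_fraction
        theta0 = rng.uniform(0, 2 * math.pi)
        span = 2 * math.pi * q
        ang = np.mod(theta - theta0, 2 * math.pi)
        mask = (rr <= spec.radius) & ~(ang < span)
        # centroid shifts opposite the removed wedge
        half = span / 2.0
        rho = (2.0 / 3.0) * spec.radius * (math.sin(half) / half) if half > 0 else 0.0
        bis = theta0 + half
        shift = -q * rho / (1.0 - q)
        center = CenterPoint(cx + shift * math.cos(bis), cy + shift * math.sin(bis))
        truth = (2 * spec.radius, math.pi * spec.radius**2 * (1 - q), q > 0)
    else:  # blob
        r_of = _radial_profile(spec, rng)
        mask = rr <= r_of(theta)
        d, area, frac = _analytic_blob_truth(r_of)
        truth = (d, area, frac > 0.5)
    return mask, center, truth


def _color_fill(
    spec: PhantomSpec, mask: np.ndarray, theta: np.ndarray
) -> np.ndarray:
    """Paint lesion pixels by angular sectors, one per requested class."""
    h, w = spec.canvas
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = spec.skin_rgb
    ang = np.mod(theta, 2 * math.pi) / (2 * math.pi)
    items = sorted(spec.color_fractions.items())
    start = 0.0
    for idx, (label, frac) in enumerate(items):
        if idx == len(items) - 1:  # last sector absorbs float remainder
            sector = mask & (ang >= start)
        else:
            sector = mask & (ang >= start) & (ang < start + frac)
        img[sector] = class_rgb(label)
        start += frac
    return img


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Render a phantom image and its ground truth; deterministic per seed."""
    h, w = spec.canvas
    rng = np.random.default_rng(spec.seed)
    mask, center, (diameter, area, asymmetric) = _lesion_mask(spec, rng)
    if not mask.any():
        raise ValueError("lesion does not intersect the canvas")
    rows, cols = np.nonzero(mask)
    if rows.min() == 0 or cols.min() == 0 or rows.max() == h - 1 or cols.max() == w - 1:
        raise ValueError("lesion touches the canvas edge; enlarge the canvas")

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    theta = np.arctan2(yy - center.y, xx - center.x)
    img = _color_fill(spec, mask, theta)

    hair_mask = np.zeros((h, w), dtype=bool)
    for _ in range(spec.hair_count):
        edge_pts = []
        for _ in range(2):
            side = rng.integers(0, 4)
            if side == 0:
                edge_pts.append((0, int(rng.integers(0, w))))
            elif side == 1:
                edge_pts.append((h - 1, int(rng.integers(0, w))))
            elif side == 2:
                edge_pts.append((int(rng.integers(0, h)), 0))
            else:
                edge_pts.append((int(rng.integers(0, h)), w - 1))
        (r0, c0), (r1, c1) = edge_pts
        if math.hypot(r1 - r0, c1 - c0) < 0.5 * min(h, w):
            continue
        rr_l, cc_l = draw_line(r0, c0, r1, c1)
        stroke = np.zeros((h, w), dtype=bool)
        stroke[rr_l, cc_l] = True
        if spec.hair_width > 1:
            stroke = ndi.binary_dilation(stroke, iterations=spec.hair_width // 2)
        hair_mask |= stroke
    img[hair_mask] = HAIR_RGB

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    x0, x1 = cols.min(), cols.max() + 1
    y0, y1 = rows.min(), rows.max() + 1
    box = BoundingBox.from_corners(float(x0), float(y0), float(x1), float(y1))
    truth = PhantomTruth(
        mask=mask,
        contour=extract_contour(mask),
        center=center,
        diameter_px=diameter,
        area_px=area,
        colors={lab for lab, f in spec.color_fractions.items() if f > 0},
        box=box,
        asymmetric=asymmetric,
        hair_mask=hair_mask,
    )
    return img, truth


# suite stratification cycles: shape recipes and color compositions
_SHAPE_CYCLE = [
    ("disk", {}),
    ("ellipse", {}),
    ("blob", {"blob_harmonics": {2: 0.10, 4: 0.06}}),  # even harmonics: symmetric
    ("notched-disk", {"notch_fraction": 0.35}),
    ("blob", {"blob_harmonics": {2: 0.06, 3: 0.22}}),  # odd harmonic: asymmetric
]
_COLOR_CYCLE = [
    {1: 1.0},
    {2: 1.0},
    {5: 1.0},
    {1: 0.5, 2: 0.5},
    {1: 0.6, 5: 0.4},
    {2: 0.4, 3: 0.35, 1: 0.25},
]


def phantom_suite(n: int, seed: int) -> list[tuple[PhantomSpec, np.ndarray, PhantomTruth]]:
    """Reproducible stratified suite: >=25% asymmetric shapes, >=25%
    multi-color compositions, and a hairy/hairless mix."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        shape, extra = _SHAPE_CYCLE[i % len(_SHAPE_CYCLE)]
        colors = _COLOR_CYCLE[i % len(_COLOR_CYCLE)]
        radius = float(rng.uniform(26.0, 38.0))
        kwargs = dict(extra)
        if shape == "ellipse":
            kwargs["semi_axes"] = (radius, float(radius / rng.uniform(1.3, 1.6)))
        spec = PhantomSpec(
            seed=int(rng.integers(0, 2**31 - 1)),
            canvas=(160, 160),
            shape=shape,
            radius=radius,
            color_fractions=dict(colors),
            hair_count=3 if i % 3 == 0 else 0,
            **kwargs,
        )
        img, truth = generate_phantom(spec)
        out.append((spec, img, truth))
    return out
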