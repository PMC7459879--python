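"""Pipeline configuration: every tunable in one validated, serializable place.

The on-disk format is a flat YAML mapping checked against the dataclass
schema; unknown keys are rejected outright — a silently ignored typo in
a threshold name would invalidate the science downstream.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # geometry / I/O
    resize: int | None = None          # square resize (px) before processing
    # hair removal
    hair_removal: bool = True
    hair_struct_len: int = 9           # linear closing element length (px)
    hair_thickness_max: float = 5.0    # max mean stroke width (px)
    hair_length_min: float = 15.0      # min stroke length (px)
    hair_median_window: int = 5        # post-repair median filter (px)
    # contrast
    equalize: bool = True
    # feed the equalized (instead of the hair-repaired) grayscale to the
    # segmenter; off by default — equalization stretches background noise
    # and collapses the block-weight separation the MST threshold needs
    segment_on_equalized: bool = False
    # ROI
    use_roi: bool = True
    roi_margin: float = 0.15           # box expansion fraction
    # segmentation
    threshold: float | None = None     # pass-I T; None = mean block weight
    block_size: int = 4
    single_pass: bool = False
    # asymmetry probing
    angle_step: float = 5.0            # degrees between probes
    asym_tol_rel: float = 0.1          # relative radius-inequality tolerance
    probe_tol_px: float = 1.5          # line-to-boundary hit tolerance (px)
    # color classification
    color_tol_h: float = 1.0           # HSV box expansion (degrees)
    color_tol_s: float = 1.0           # (percent points)
    color_tol_v: float = 1.0           # (percent points)
    min_color_pixels: int = 20         # pixels for a class to be reported
    # physical scaling
    focal_mm: float | None = None
    distance_mm: float | None = None
    pixel_pitch: float | None = None   # mm per pixel on the image plane

    def __post_init__(self) -> None:
        if self.threshold is not None and self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")
        if self.angle_step <= 0 or (180.0 / self.angle_step) != int(
            180.0 / self.angle_step
        ):
            raise ValueError("angle_step must divide 180")
        if not (0.0 <= self.asym_tol_rel <= 1.0):
            raise ValueError("asym_tol_rel must be in [0, 1]")
        for name in ("focal_mm", "distance_mm", "pixel_pitch"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when given")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must be a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
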