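"""Raster image and binary-mask containers with PNG/JPEG/BMP I/O.

Images are plain numpy ``uint8`` arrays: ``(H, W)`` for grayscale,
``(H, W, 3)`` for RGB.  Binary masks are boolean ``(H, W)`` arrays,
stored on disk as single-channel PNG with values {0, 255}.
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image

__all__ = [
    "validate_image",
    "validate_mask",
    "load_image",
    "save_image",
    "read_mask",
    "write_mask",
]


def validate_image(img: np.ndarray) -> np.ndarray:
    """Check an array is a valid 8-bit raster image and return it as uint8."""
    arr = np.asarray(img)
    if arr.ndim not in (2, 3):
        raise ValueError(f"image must be 2-D or 3-D, got ndim={arr.ndim}")
    if arr.ndim == 3 and arr.shape[2] != 3:
        raise ValueError(f"color image must have 3 channels, got {arr.shape[2]}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must have positive height and width")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise ValueError("image values must be integers in [0, 255]")
    return arr


def validate_mask(mask: np.ndarray, like: np.ndarray | None = None) -> np.ndarray:
    """Check a boolean mask, optionally against a reference image's shape."""
    m = np.asarray(mask)
    if m.dtype != bool:
        raise ValueError("mask must be boolean")
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    if like is not None and m.shape != np.asarray(like).shape[:2]:
        raise ValueError(f"mask shape {m.shape} does not match image {like.shape[:2]}")
    return m


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read an 8-bit image file; palette/alpha images are flattened to RGB."""
    with Image.open(path) as im:
        if im.mode in ("1", "L"):
            im = im.convert("L")
            return np.asarray(im, dtype=np.uint8)
        im = im.convert("RGB")
        return np.asarray(im, dtype=np.uint8)


def save_image(path: str | os.PathLike, img: np.ndarray) -> None:
    img = validate_image(img)
    Image.fromarray(img).save(path)


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a single-channel PNG mask; values >= 128 map to True.

    Multi-channel files are rejected: a mask must be unambiguous.
    """
    with Image.open(path) as im:
        if im.mode not in ("1", "L"):
            raise ValueError(
                f"mask file must be single-channel, got mode {im.mode!r}: {path}"
            )
        arr = np.asarray(im.convert("L"), dtype=np.uint8)
    return arr >= 128


def write_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    mask = validate_mask(mask)
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8), mode="L").save(path)
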