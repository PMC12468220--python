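"""Loading and saving of 8-bit raster images (PNG, BMP, TIFF).

Images are carried through the pipeline as float64 arrays in [0, 1]
(single-channel ``(H, W)`` or RGB ``(H, W, 3)``); quantization to 8-bit
happens only here, with round-half-to-even then clamping, so no stage
accumulates quantization error.  Binary masks serialize as {0, 255} PNGs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["load_image", "save_image", "load_mask", "save_mask", "to_uint8"]


def load_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale or RGB image, normalized to [0, 1].

    Alpha channels are dropped with a warning.  Bit depths other than 8 are
    rejected.
    """
    arr = iio.imread(Path(path))
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: only 8-bit images are supported, got dtype {arr.dtype}")
    if arr.ndim == 3 and arr.shape[-1] == 4:
        logger.warning("%s: alpha channel dropped", path)
        arr = arr[..., :3]
    if arr.ndim == 3 and arr.shape[-1] not in (1, 3):
        raise ValueError(f"{path}: unsupported channel count {arr.shape[-1]}")
    if arr.ndim == 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    if arr.ndim not in (2, 3):
        raise ValueError(f"{path}: unsupported image shape {arr.shape}")
    return arr.astype(np.float64) / 255.0


def to_uint8(img: np.ndarray) -> np.ndarray:
    """Quantize a [0, 1] float image to 8-bit (round half to even, clamp)."""
    return np.clip(np.rint(np.asarray(img, dtype=np.float64) * 255.0), 0, 255).astype(np.uint8)


def save_image(path: str | Path, img: np.ndarray) -> None:
    """Write a [0, 1] float image as an 8-bit file (format from extension)."""
    iio.imwrite(Path(path), to_uint8(img))


def load_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask; any nonzero pixel is foreground."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit {0, 255} image (white = nucleus)."""
    mask = np.asarray(mask, dtype=bool)
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))
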