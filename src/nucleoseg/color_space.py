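"""Exact RGB <-> HSV conversion on the hexcone model.

The segmentation pipeline enhances the Value channel of stained cytology
images, so the conversion must be a true round trip: ``hsv_to_rgb`` is the
exact inverse of ``rgb_to_hsv`` (to floating-point precision).  Hue is in
degrees in [0, 360), saturation and value are unitless in [0, 1], and all RGB
channels live in normalized [0, 1]; scaling to 8-bit happens only at
serialization (:mod:`nucleoseg.image_io`).

Conventions for degenerate pixels: an achromatic pixel (R = G = B) has S = 0
and H = 0; a black pixel (V = 0) additionally has S = 0.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["rgb_to_hsv", "hsv_to_rgb"]


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image must have height >= 1 and width >= 1")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("RGB channels must be normalized to [0, 1]")
    return img


def rgb_to_hsv(img: np.ndarray) -> np.ndarray:
    """Convert a normalized RGB image to HSV.

    Parameters
    ----------
    img
        ``(H, W, 3)`` array with channels in [0, 1].

    Returns
    -------
    ``(H, W, 3)`` array: hue in degrees [0, 360), saturation and value in
    [0, 1].  V is ``max(R, G, B)`` per pixel; S is the relative chroma
    ``(V - min) / V`` (0 where V = 0); H follows the standard hexcone sector
    formula, 0 at achromatic pixels.
    """
    img = _check_rgb(img)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    v = img.max(axis=-1)
    mn = img.min(axis=-1)
    c = v - mn  # chroma

    safe_v = np.where(v > 0.0, v, 1.0)
    s = np.where(v > 0.0, c / safe_v, 0.0)

    safe_c = np.where(c > 0.0, c, 1.0)
    h = np.zeros_like(v)
    chromatic = c > 0.0
    is_r = chromatic & (v == r)
    is_g = chromatic & ~is_r & (v == g)
    is_b = chromatic & ~is_r & ~is_g
    h = np.where(is_r, 60.0 * (((g - b) / safe_c) % 6.0), h)
    h = np.where(is_g, 60.0 * ((b - r) / safe_c + 2.0), h)
    h = np.where(is_b, 60.0 * ((r - g) / safe_c + 4.0), h)
    # (g - b) / c mod 6 can land exactly on 6.0 through rounding
    h = np.where(h >= 360.0, h - 360.0, h)
    return np.stack([h, s, v], axis=-1)


def hsv_to_rgb(img: np.ndarray) -> np.ndarray:
    """Convert an HSV image (H in degrees, S and V in [0, 1]) back to RGB.

    The reconstruction goes through chroma ``C = V*S``, the intensity
    adjustment ``X = C * (1 - |(H/60) mod 2 - 1|)`` and the brightness
    matching value ``m = V - C``, assigning (R', G', B') by 60-degree hue
    sector and returning (R' + m, G' + m, B' + m).

    Hue values outside [0, 360) are wrapped by modulo with a logged warning;
    S or V outside [0, 1] are rejected.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) HSV array, got shape {img.shape}")
    h, s, v = img[..., 0], img[..., 1], img[..., 2]
    if s.min() < 0.0 or s.max() > 1.0:
        raise ValueError("saturation must be in [0, 1]")
    if v.min() < 0.0 or v.max() > 1.0:
        raise ValueError("value must be in [0, 1]")
    if h.min() < 0.0 or h.max() >= 360.0:
        logger.warning("hue outside [0, 360) wrapped by modulo")
        h = np.mod(h, 360.0)

    c = v * s
    hp = h / 60.0
    x = c * (1.0 - np.abs(np.mod(hp, 2.0) - 1.0))
    m = v - c

    sector = np.floor(hp).astype(int)  # 0..5
    sector = np.clip(sector, 0, 5)
    zero = np.zeros_like(c)
    # (R', G', B') per sector, in sector order 0..5
    rp = np.choose(sector, [c, x, zero, zero, x, c])
    gp = np.choose(sector, [x, c, c, x, zero, zero])
    bp = np.choose(sector, [zero, zero, x, c, c, x])
    return np.stack([rp + m, gp + m, bp + m], axis=-1)
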