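"""Preprocessing stage: bilateral filtering and adaptive gamma correction.

Stained cytology images vary widely in exposure, so the pipeline measures
the mean of the (bilaterally filtered) V channel and picks a gamma from it:

* mean > 0.5:  gamma = 1 + (0.5 - mean)
* mean <= 0.5: gamma = 1 / (2 * mean)

Both branches give gamma = 1 at mean = 0.5, so the correction is continuous.
Because the published branch labels and the branch formulas pull in opposite
directions (see docs/methods.md), a ``convention`` switch selects either the
formula-per-branch mapping above (``"equations"``, the default) or the
swapped mapping (``"prose"``).

The bilateral filter is a windowed weighted mean whose weights combine an
unnormalized spatial Gaussian and an unnormalized range (intensity) Gaussian,
so edges — nucleus/cytoplasm boundaries — survive the smoothing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .color_space import hsv_to_rgb, rgb_to_hsv

logger = logging.getLogger(__name__)

__all__ = [
    "BilateralParams",
    "GammaDecision",
    "EnhancementResult",
    "bilateral_filter",
    "mean_intensity",
    "adaptive_gamma",
    "apply_gamma",
    "enhance",
]

GAMMA_CONVENTIONS = ("equations", "prose")


@dataclass(frozen=True)
class BilateralParams:
    """Bilateral filter parameters.

    ``spatial_sigma`` (pixels) and ``range_sigma`` (intensity units on the
    [0, 1] scale) must be positive.  ``window_radius`` defaults to
    ``ceil(2 * spatial_sigma)`` so the spatial kernel is not truncated early.
    """

    spatial_sigma: float = 3.0
    range_sigma: float = 0.1
    window_radius: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.spatial_sigma <= 0 or self.range_sigma <= 0:
            raise ValueError("bilateral sigmas must be positive")
        if self.window_radius < 0:
            object.__setattr__(self, "window_radius", max(1, math.ceil(2.0 * self.spatial_sigma)))
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")


@dataclass(frozen=True)
class GammaDecision:
    """Outcome of the adaptive gamma rule, kept for run logging."""

    mean_intensity: float
    gamma: float
    branch: str  # "above_half" or "at_or_below_half"


@dataclass(frozen=True)
class EnhancementResult:
    """Enhanced RGB image plus the measured mean and chosen gamma."""

    image: np.ndarray
    filtered_v: np.ndarray
    decision: GammaDecision


def _check_channel(channel: np.ndarray) -> np.ndarray:
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 2 or channel.size == 0:
        raise ValueError(f"expected a non-empty 2-D channel, got shape {channel.shape}")
    if channel.min() < 0.0 or channel.max() > 1.0:
        raise ValueError("channel values must be in [0, 1]")
    return channel


def bilateral_filter(channel: np.ndarray, params: BilateralParams | None = None) -> np.ndarray:
    """Edge-preserving smoothing of a single channel.

    Each output pixel is the window-weighted mean of its (2r+1)^2 mirror-padded
    neighborhood, weights = spatial Gaussian of the offset times range Gaussian
    of the intensity difference to the center pixel.  A constant image is an
    exact fixed point.
    """
    channel = _check_channel(channel)
    if params is None:
        params = BilateralParams()
    r = params.window_radius
    two_ss2 = 2.0 * params.spatial_sigma**2
    two_sr2 = 2.0 * params.range_sigma**2

    padded = np.pad(channel, r, mode="reflect")
    h, w = channel.shape
    # accumulate sum of w*(neighbor - center); adding it back to the center
    # keeps constant regions bitwise unchanged
    num = np.zeros_like(channel)
    den = np.zeros_like(channel)
    for di in range(-r, r + 1):
        for dj in range(-r, r + 1):
            gs = math.exp(-(di * di + dj * dj) / two_ss2)
            shifted = padded[r + di : r + di + h, r + dj : r + dj + w]
            diff = shifted - channel
            weight = gs * np.exp(-(diff * diff) / two_sr2)
            num += weight * diff
            den += weight
    return channel + num / den


def mean_intensity(channel: np.ndarray) -> float:
    """Mean of a [0, 1] channel over all pixels."""
    return float(np.mean(_check_channel(channel)))


def adaptive_gamma(
    mean: float,
    convention: str = "equations",
    gamma_max: float = 5.0,
) -> GammaDecision:
    """Pick a gamma exponent from the mean V intensity.

    Under the default ``equations`` convention, mean > 0.5 uses
    gamma = 1 + (0.5 - mean) and mean <= 0.5 uses gamma = 1/(2*mean); the
    ``prose`` convention swaps the two formulas between the branches.  The
    hyperbolic branch diverges as mean -> 0, so gamma is clamped to
    ``gamma_max`` with a warning.
    """
    if not 0.0 <= mean <= 1.0:
        raise ValueError("mean intensity must be in [0, 1]")
    if convention not in GAMMA_CONVENTIONS:
        raise ValueError(f"unknown gamma convention {convention!r}")

    linear = 1.0 + (0.5 - mean)  # in [0.5, 1.5]
    hyperbolic = math.inf if mean == 0.0 else 1.0 / (2.0 * mean)
    if convention == "equations":
        branch = "above_half" if mean > 0.5 else "at_or_below_half"
        gamma = linear if mean > 0.5 else hyperbolic
    else:  # prose: brighten-the-dark reading, formulas swapped
        branch = "above_half" if mean > 0.5 else "at_or_below_half"
        gamma = hyperbolic if mean > 0.5 else linear

    if gamma > gamma_max:
        logger.warning("gamma %.3g clamped to %.3g (mean intensity %.4f)", gamma, gamma_max, mean)
        gamma = gamma_max
    return GammaDecision(mean_intensity=mean, gamma=gamma, branch=branch)


def apply_gamma(channel: np.ndarray, gamma: float) -> np.ndarray:
    """Per-pixel power-law transform ``V -> V**gamma`` on [0, 1]."""
    channel = _check_channel(channel)
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if gamma == 1.0:
        return channel.copy()
    return np.power(channel, gamma)


def enhance(
    img: np.ndarray,
    params: BilateralParams | None = None,
    convention: str = "equations",
    gamma_max: float = 5.0,
) -> EnhancementResult:
    """Full preprocessing stage on an RGB image.

    Converts to HSV, bilaterally filters V, measures the filtered mean,
    chooses the adaptive gamma, applies it to the filtered V, and reassembles
    RGB with the original H and S.
    """
    hsv = rgb_to_hsv(img)
    filtered_v = bilateral_filter(hsv[..., 2], params)
    mean = mean_intensity(filtered_v)
    decision = adaptive_gamma(mean, convention=convention, gamma_max=gamma_max)
    logger.info(
        "enhance: mean V = %.4f, branch = %s, gamma = %.4f",
        mean, decision.branch, decision.gamma,
    )
    corrected = apply_gamma(filtered_v, decision.gamma)
    out_hsv = np.stack([hsv[..., 0], hsv[..., 1], corrected], axis=-1)
    return EnhancementResult(image=hsv_to_rgb(out_hsv), filtered_v=filtered_v, decision=decision)
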