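"""Three-class multi-Otsu thresholding of the enhanced grayscale image.

The enhanced RGB image is reduced to BT.601 luminance, quantized to 256
levels, and its normalized histogram p(i) is split into three intensity
classes — nuclei (darkest), cytoplasm, background — by the threshold pair
(t1, t2) that maximizes the between-class variance

    sigma_B^2 = sum_k omega_k * (mu_k - mu_T)^2,      k in {1, 2, 3}

with class ranges [0, t1], [t1+1, t2], [t2+1, 255].  The search uses
cumulative moments over all admissible pairs and is tie-broken to the
lexicographically smallest (t1, t2), so it is exactly reproducible and
agrees with exhaustive enumeration.  Class 1 (darkest) is extracted as the
nucleus mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "BT601_WEIGHTS",
    "IntensityHistogram",
    "ThresholdPair",
    "OtsuClassStats",
    "to_grayscale",
    "quantize_u8",
    "compute_histogram",
    "class_stats",
    "multi_otsu",
    "extract_class_mask",
]

L = 256
BT601_WEIGHTS = (0.299, 0.587, 0.114)


class ThresholdPair(NamedTuple):
    """Gray-level thresholds 0 <= t1 < t2 <= 254 bounding three classes."""

    t1: int
    t2: int


def _check_pair(t: ThresholdPair) -> ThresholdPair:
    t = ThresholdPair(int(t[0]), int(t[1]))
    if not (0 <= t.t1 < t.t2 <= L - 2):
        raise ValueError(f"need 0 <= t1 < t2 <= {L - 2}, got {t}")
    return t


@dataclass(frozen=True)
class IntensityHistogram:
    """Normalized 256-bin intensity distribution with its global moments."""

    p: np.ndarray  # shape (256,), sums to 1
    mean: float  # mu_T, gray levels
    variance: float  # sigma_T^2, gray levels squared

    @classmethod
    def from_probabilities(cls, p: np.ndarray) -> "IntensityHistogram":
        p = np.asarray(p, dtype=np.float64)
        if p.shape != (L,):
            raise ValueError(f"expected {L} bins, got shape {p.shape}")
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("bins must be non-negative and sum to 1")
        idx = np.arange(L, dtype=np.float64)
        mean = float(np.sum(idx * p))
        variance = float(np.sum((idx - mean) ** 2 * p))
        return cls(p=p, mean=mean, variance=variance)


@dataclass(frozen=True)
class OtsuClassStats:
    """Per-class probabilities and means, with the variance decomposition."""

    omega: np.ndarray  # shape (3,)
    mu: np.ndarray  # shape (3,); 0 where the class is empty
    sigma_b: float  # between-class variance
    sigma_w: float  # within-class variance


def to_grayscale(img: np.ndarray, weights: tuple[float, float, float] = BT601_WEIGHTS) -> np.ndarray:
    """BT.601 luminance of a normalized RGB image, float in [0, 1]."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[-1] != 3 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {img.shape}")
    w = np.asarray(weights, dtype=np.float64)
    return img @ w


def quantize_u8(channel: np.ndarray) -> np.ndarray:
    """Quantize a [0, 1] channel to integer levels 0..255 via floor(v*255 + 0.5)."""
    channel = np.clip(np.asarray(channel, dtype=np.float64), 0.0, 1.0)
    return np.floor(channel * 255.0 + 0.5).astype(np.uint8)


def compute_histogram(levels: np.ndarray) -> IntensityHistogram:
    """Normalized histogram of an integer-level (0..255) image."""
    levels = np.asarray(levels)
    if levels.size == 0:
        raise ValueError("cannot histogram an empty image")
    if not np.issubdtype(levels.dtype, np.integer):
        raise ValueError("expected integer gray levels; quantize with quantize_u8 first")
    counts = np.bincount(levels.ravel(), minlength=L).astype(np.float64)
    return IntensityHistogram.from_probabilities(counts / levels.size)


def class_stats(h: IntensityHistogram, t: ThresholdPair) -> OtsuClassStats:
    """Class probabilities/means and the between/within-class variances.

    Empty classes (omega_k = 0) contribute 0 to both variances.
    """
    t = _check_pair(t)
    idx = np.arange(L, dtype=np.float64)
    edges = [(0, t.t1 + 1), (t.t1 + 1, t.t2 + 1), (t.t2 + 1, L)]
    omega = np.empty(3)
    mu = np.zeros(3)
    var_within = 0.0
    for k, (lo, hi) in enumerate(edges):
        pk = h.p[lo:hi]
        ik = idx[lo:hi]
        omega[k] = pk.sum()
        if omega[k] > 0:
            mu[k] = float(np.sum(ik * pk) / omega[k])
            var_within += float(np.sum((ik - mu[k]) ** 2 * pk))
    sigma_b = float(np.sum(omega * (mu - h.mean) ** 2))
    return OtsuClassStats(omega=omega, mu=mu, sigma_b=sigma_b, sigma_w=var_within)


def multi_otsu(h: IntensityHistogram) -> ThresholdPair:
    """Threshold pair maximizing the between-class variance.

    Computed with cumulative moments over the full (t1, t2) grid; ties are
    broken to the smallest t1, then the smallest t2, matching exhaustive
    enumeration exactly.  Requires at least three occupied gray levels.
    """
    if np.count_nonzero(h.p) < 3:
        raise ValueError(
            "histogram has fewer than 3 occupied levels; three-class thresholding "
            "is degenerate (use two-class Otsu or handle constant images upstream)"
        )
    idx = np.arange(L, dtype=np.float64)
    cp = np.cumsum(h.p)
    cm = np.cumsum(idx * h.p)
    mu_t = h.mean

    t1 = np.arange(L - 1)  # 0..254
    t2 = np.arange(L - 1)
    w1 = cp[t1][:, None]
    m1 = cm[t1][:, None]
    w12 = cp[t2][None, :]
    m12 = cm[t2][None, :]
    w2 = w12 - w1
    m2 = m12 - m1
    w3 = 1.0 - w12
    m3 = cm[-1] - m12

    def contrib(w: np.ndarray, m: np.ndarray) -> np.ndarray:
        mu = np.divide(m, w, out=np.zeros_like(m + w), where=w > 0)
        return np.where(w > 0, w * (mu - mu_t) ** 2, 0.0)

    sigma_b = contrib(w1, m1) + contrib(w2, m2) + contrib(w3, m3)
    invalid = t1[:, None] >= t2[None, :]
    sigma_b[invalid] = -np.inf
    flat = int(np.argmax(sigma_b))  # row-major => lexicographic tie-break
    return ThresholdPair(flat // (L - 1), flat % (L - 1))


def extract_class_mask(levels: np.ndarray, t: ThresholdPair, class_index: int = 0) -> np.ndarray:
    """Binary mask of one intensity class (default: class 0, the darkest).

    For cytology images the darkest class [0, t1] is the nucleus class;
    ``class_index`` 1 and 2 select the cytoplasm and background ranges.
    """
    t = _check_pair(t)
    levels = np.asarray(levels)
    if class_index == 0:
        return levels <= t.t1
    if class_index == 1:
        return (levels > t.t1) & (levels <= t.t2)
    if class_index == 2:
        return levels > t.t2
    raise ValueError("class_index must be 0, 1, or 2")
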