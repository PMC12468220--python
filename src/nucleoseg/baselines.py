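"""Classical local adaptive binarizers: Bradley, Feng, Niblack, Nick, Sauvola.

All five derive a per-pixel threshold T from sliding-window statistics — the
local mean m and (for all but Bradley) the local standard deviation s — and
mark a pixel as foreground where its intensity falls below T (dark-object
convention, matching dark nuclei on a bright background):

    Bradley   T = m * (1 - k/100)                       k = 12
    Niblack   T = m + k * s                             k = -0.2
    Nick      T = m + k * sqrt((sum_w I^2 - m^2) / N)   k = -0.13
    Sauvola   T = m * (1 - k * (1 - s / R))             k = 0.1, R = 128
    Feng      T = (1 - a1) * m + a2 * (s / Rs) * (m - M) + a3 * M
              a2 = k1 * (s / Rs)^g,  a3 = k2 * (s / Rs)^g

Statistics are computed over (2r+1)^2 windows cropped at the image borders,
using integral images of I and I^2 for O(1) window sums.  Inputs are 8-bit
gray levels (0..255), the scale the canonical constants assume; integer
accumulation makes the integral path bit-exact against direct summation.

Feng needs two windows: the primary one for m, s, and the local minimum M,
and a secondary (larger) one for Rs, the dynamic range of the standard
deviation (the maximum of s over the secondary window).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = ["METHODS", "BaselineParams", "WindowStats", "integral_image",
           "window_stats", "threshold_surface", "local_threshold"]

METHODS = ("bradley", "feng", "niblack", "nick", "sauvola")


@dataclass(frozen=True)
class BaselineParams:
    """Method selector plus the per-method constants (canonical defaults)."""

    method: str = "sauvola"
    window_radius: int = 15
    bradley_k: float = 12.0  # percent below the local mean
    niblack_k: float = -0.2
    nick_k: float = -0.13
    sauvola_k: float = 0.1
    sauvola_r: float = 128.0  # gray-level dynamic range of s
    feng_alpha1: float = 0.12
    feng_gamma: float = 2.0
    feng_k1: float = 0.25
    feng_k2: float = 0.04
    feng_secondary_scale: int = 2  # secondary radius = scale * window_radius
    invert: bool = False  # True: bright-object convention

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")


@dataclass(frozen=True)
class WindowStats:
    """Per-pixel cropped-window mean, standard deviation, and pixel count."""

    mean: np.ndarray
    std: np.ndarray
    count: np.ndarray
    window_radius: int


def _as_levels(channel: np.ndarray) -> np.ndarray:
    """Coerce input to integer gray levels 0..255."""
    channel = np.asarray(channel)
    if channel.ndim != 2 or channel.size == 0:
        raise ValueError(f"expected a non-empty 2-D channel, got shape {channel.shape}")
    if np.issubdtype(channel.dtype, np.integer):
        if channel.min() < 0 or channel.max() > 255:
            raise ValueError("integer levels must be in 0..255")
        return channel.astype(np.int64)
    channel = channel.astype(np.float64)
    if channel.min() < 0.0 or channel.max() > 1.0:
        raise ValueError("float channels must be normalized to [0, 1]")
    return np.floor(channel * 255.0 + 0.5).astype(np.int64)


def integral_image(channel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero-padded cumulative-sum tables of I and I^2 (exact, int64).

    The returned arrays have shape (H+1, W+1); the sum over rows [r0, r1) and
    columns [c0, c1) is ``ii[r1, c1] - ii[r0, c1] - ii[r1, c0] + ii[r0, c0]``.
    """
    levels = _as_levels(channel)
    h, w = levels.shape
    ii = np.zeros((h + 1, w + 1), dtype=np.int64)
    ii2 = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(levels, axis=0), axis=1, out=ii[1:, 1:])
    np.cumsum(np.cumsum(levels * levels, axis=0), axis=1, out=ii2[1:, 1:])
    return ii, ii2


def _window_sums(table: np.ndarray, radius: int) -> np.ndarray:
    h, w = table.shape[0] - 1, table.shape[1] - 1
    rows = np.arange(h)
    cols = np.arange(w)
    r0 = np.clip(rows - radius, 0, h)[:, None]
    r1 = np.clip(rows + radius + 1, 0, h)[:, None]
    c0 = np.clip(cols - radius, 0, w)[None, :]
    c1 = np.clip(cols + radius + 1, 0, w)[None, :]
    return table[r1, c1] - table[r0, c1] - table[r1, c0] + table[r0, c0]


def window_stats(channel: np.ndarray, radius: int) -> WindowStats:
    """Cropped-window local mean and population standard deviation."""
    levels = _as_levels(channel)
    h, w = levels.shape
    if (2 * radius + 1) ** 2 < 9:
        raise ValueError("window must cover at least 9 pixels")
    if 2 * radius + 1 > max(h, w):
        raise ValueError("window larger than the image")
    ii, ii2 = integral_image(levels)
    s1 = _window_sums(ii, radius)
    s2 = _window_sums(ii2, radius)
    rows = np.arange(h)
    cols = np.arange(w)
    nr = (np.clip(rows + radius + 1, 0, h) - np.clip(rows - radius, 0, h))[:, None]
    nc = (np.clip(cols + radius + 1, 0, w) - np.clip(cols - radius, 0, w))[None, :]
    n = (nr * nc).astype(np.float64)
    mean = s1 / n
    var = s2 / n - mean * mean
    std = np.sqrt(np.maximum(var, 0.0))
    return WindowStats(mean=mean, std=std, count=n, window_radius=radius)


def threshold_surface(channel: np.ndarray, params: BaselineParams) -> np.ndarray:
    """Per-pixel threshold T for the selected method, on the 0..255 scale."""
    levels = _as_levels(channel)
    ws = window_stats(levels, params.window_radius)
    m, s, n = ws.mean, ws.std, ws.count

    if params.method == "bradley":
        return m * (1.0 - params.bradley_k / 100.0)
    if params.method == "niblack":
        return m + params.niblack_k * s
    if params.method == "nick":
        # canonical NICK: sqrt of (window sum of I^2 minus m^2) over N
        ii, ii2 = integral_image(levels)
        s2 = _window_sums(ii2, params.window_radius)
        return m + params.nick_k * np.sqrt(np.maximum((s2 - m * m) / n, 0.0))
    if params.method == "sauvola":
        return m * (1.0 - params.sauvola_k * (1.0 - s / params.sauvola_r))
    # feng
    flo = levels.astype(np.float64)
    size = 2 * params.window_radius + 1
    local_min = ndi.minimum_filter(flo, size=size, mode="constant", cval=np.inf)
    sec = params.feng_secondary_scale * params.window_radius
    rs = ndi.maximum_filter(s, size=2 * sec + 1, mode="constant", cval=-np.inf)
    rs_safe = np.where(rs > 0.0, rs, 1.0)
    ratio = s / rs_safe
    a2 = params.feng_k1 * ratio**params.feng_gamma
    a3 = params.feng_k2 * ratio**params.feng_gamma
    return (1.0 - params.feng_alpha1) * m + a2 * ratio * (m - local_min) + a3 * local_min


def local_threshold(channel: np.ndarray, params: BaselineParams) -> np.ndarray:
    """Binarize with the selected method; True marks the dark (nucleus) side.

    With ``params.invert`` the bright side is marked instead.
    """
    levels = _as_levels(channel)
    t = threshold_surface(levels, params)
    mask = levels < t
    return ~mask if params.invert else mask
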