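"""Independent reference implementations (oracles) used by the test suite.

These deliberately take the slow, literal route — double/quadruple loops,
breadth-first flood fill, exhaustive enumeration — so they share no code
path with the package implementations they check.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def naive_bilateral(channel: np.ndarray, spatial_sigma: float, range_sigma: float,
                    radius: int) -> np.ndarray:
    """Direct quadruple-loop weighted average over the mirror-padded window."""
    pad = np.pad(channel, radius, mode="reflect").tolist()
    h, w = channel.shape
    out = np.empty_like(channel, dtype=np.float64)
    two_ss2 = 2.0 * spatial_sigma * spatial_sigma
    two_sr2 = 2.0 * range_sigma * range_sigma
    spatial = {
        (di, dj): math.exp(-(di * di + dj * dj) / two_ss2)
        for di in range(-radius, radius + 1)
        for dj in range(-radius, radius + 1)
    }
    for y in range(h):
        for x in range(w):
            center = pad[y + radius][x + radius]
            num = 0.0
            den = 0.0
            for (di, dj), gs in spatial.items():
                v = pad[y + radius + di][x + radius + dj]
                d = v - center
                wgt = gs * math.exp(-(d * d) / two_sr2)
                num += wgt * v
                den += wgt
            out[y, x] = num / den
    return out


def truncated_gaussian_smooth(channel: np.ndarray, sigma: float, radius: int) -> np.ndarray:
    """Plain spatial Gaussian smoothing with the same truncated window."""
    from scipy import ndimage as ndi

    offsets = np.arange(-radius, radius + 1)
    dd = offsets[:, None] ** 2 + offsets[None, :] ** 2
    kernel = np.exp(-dd / (2.0 * sigma * sigma))
    kernel /= kernel.sum()
    # scipy "mirror" == np.pad "reflect", the package's border policy
    return ndi.correlate(channel.astype(np.float64), kernel, mode="mirror")


def exhaustive_multiotsu(p: np.ndarray) -> tuple[int, int]:
    """Enumerate every admissible (t1, t2) pair; first strict maximum wins.

    Uses the algebraic form sum_k m_k^2/w_k - mu_T^2, a different route from
    the package's sum_k w_k (mu_k - mu_T)^2 broadcast.
    """
    idx = np.arange(256, dtype=np.float64)
    cp = np.cumsum(p).tolist()
    cm = np.cumsum(idx * p).tolist()
    mu_t = cm[-1]
    best_val = -math.inf
    best = None
    for t1 in range(0, 254):
        w1 = cp[t1]
        m1 = cm[t1]
        for t2 in range(t1 + 1, 255):
            w2 = cp[t2] - w1
            m2 = cm[t2] - m1
            w3 = 1.0 - cp[t2]
            m3 = mu_t - cm[t2]
            val = -mu_t * mu_t
            if w1 > 0.0:
                val += m1 * m1 / w1
            if w2 > 0.0:
                val += m2 * m2 / w2
            if w3 > 0.0:
                val += m3 * m3 / w3
            if val > best_val:
                best_val = val
                best = (t1, t2)
    return best


def flood_fill_labels(mask: np.ndarray) -> np.ndarray:
    """4-connected component labels by breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    h, w = mask.shape
    current = 0
    for sy in range(h):
        for sx in range(w):
            if mask[sy, sx] and labels[sy, sx] == 0:
                current += 1
                queue = deque([(sy, sx)])
                labels[sy, sx] = current
                while queue:
                    y, x = queue.popleft()
                    for ny, nx in ((y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1)):
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and labels[ny, nx] == 0:
                            labels[ny, nx] = current
                            queue.append((ny, nx))
    return labels


def naive_threshold_surface(levels: np.ndarray, params) -> np.ndarray:
    """Per-pixel thresholds by direct cropped-window gathering (no integrals)."""
    levels = np.asarray(levels, dtype=np.int64)
    h, w = levels.shape
    r = params.window_radius

    def window(arr, y, x, radius):
        return arr[max(0, y - radius):y + radius + 1, max(0, x - radius):x + radius + 1]

    mean = np.empty((h, w))
    std = np.empty((h, w))
    count = np.empty((h, w))
    s2map = np.empty((h, w))
    for y in range(h):
        for x in range(w):
            win = window(levels, y, x, r)
            n = float(win.size)
            s1 = int(win.sum())
            s2 = int((win * win).sum())
            m = s1 / n
            var = s2 / n - m * m
            mean[y, x] = m
            std[y, x] = math.sqrt(max(var, 0.0))
            count[y, x] = n
            s2map[y, x] = s2

    if params.method == "bradley":
        return mean * (1.0 - params.bradley_k / 100.0)
    if params.method == "niblack":
        return mean + params.niblack_k * std
    if params.method == "nick":
        return mean + params.nick_k * np.sqrt(np.maximum((s2map - mean * mean) / count, 0.0))
    if params.method == "sauvola":
        return mean * (1.0 - params.sauvola_k * (1.0 - std / params.sauvola_r))
    # feng: primary-window min, secondary-window max of the std map
    flo = levels.astype(np.float64)
    sec = params.feng_secondary_scale * r
    t = np.empty((h, w))
    for y in range(h):
        for x in range(w):
            local_min = float(window(flo, y, x, r).min())
            rs = float(window(std, y, x, sec).max())
            rs_safe = rs if rs > 0.0 else 1.0
            ratio = std[y, x] / rs_safe
            a2 = params.feng_k1 * ratio**params.feng_gamma
            a3 = params.feng_k2 * ratio**params.feng_gamma
            t[y, x] = ((1.0 - params.feng_alpha1) * mean[y, x]
                       + a2 * ratio * (mean[y, x] - local_min) + a3 * local_min)
    return t


def naive_local_threshold(levels: np.ndarray, params) -> np.ndarray:
    levels = np.asarray(levels, dtype=np.int64)
    mask = levels < naive_threshold_surface(levels, params)
    return ~mask if params.invert else mask


def random_histogram(rng: np.random.Generator, spiky: bool = False) -> np.ndarray:
    """Random normalized 256-bin histogram; spiky ones have many empty bins."""
    if spiky:
        n_spikes = int(rng.integers(3, 12))
        positions = rng.choice(256, size=n_spikes, replace=False)
        weights = rng.uniform(0.1, 1.0, n_spikes)
        p = np.zeros(256)
        p[positions] = weights
    else:
        p = rng.uniform(0.0, 1.0, 256)
    return p / p.sum()
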