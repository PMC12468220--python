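"""Seed-controlled generator of Pap-smear-like images with ground truth.

Real Pap smear fields show dark hematoxylin-stained nuclei inside lighter
cytoplasm on a bright background — a three-mode intensity structure that is
exactly the regime three-class Otsu thresholding assumes.  The generator
renders that structure directly: each cell is a rotated nucleus ellipse
inside a larger cytoplasm ellipse, composited dark-over-light onto a bright
background, colorized with a purple-magenta stain hue in HSV, and then
degraded by an illumination gradient, Gaussian blur, and additive Gaussian
noise (in that order, clamped to [0, 1] afterwards).

The returned ground-truth mask is the exact rasterized union of the nucleus
ellipses, built before any degradation.  Identical ``SceneSpec`` (including
its seed) always reproduces bitwise-identical outputs.

Default intensities (nucleus 0.15 +/- 0.05, cytoplasm 0.55 +/- 0.05,
background 0.85) keep the three modes well separated at realistic stain
contrast; what the generator deliberately does not emulate (chromatin
texture, debris, leukocytes) is documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import image_io
from .color_space import hsv_to_rgb

__all__ = ["SceneSpec", "generate_scene", "degrade", "make_fixture_suite", "spec_from_row"]


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic scene; with ``seed`` it is the image."""

    height: int = 128
    width: int = 128
    n_nuclei: int = 4
    nucleus_axis_min: float = 5.0  # semi-axis, pixels
    nucleus_axis_max: float = 10.0
    nucleus_intensity: float = 0.15
    nucleus_jitter: float = 0.05
    cytoplasm_intensity: float = 0.55
    cytoplasm_jitter: float = 0.05
    background_intensity: float = 0.85
    cytoplasm_scale: float = 2.2  # cytoplasm semi-axes = scale * nucleus axes
    overlap_fraction: float = 0.0  # 0 = disjoint nuclei, 1 = unconstrained
    illumination_gradient: float = 0.0  # peak-to-peak amplitude, [0, 0.3]
    noise_sigma: float = 0.01
    blur_sigma: float = 0.8  # pixels
    stain_hue: float = 290.0  # degrees; purple-magenta
    cell_saturation: float = 0.35
    background_saturation: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError("scene must be at least 16x16")
        if self.n_nuclei < 1:
            raise ValueError("need at least one nucleus")
        if not 0 < self.nucleus_axis_min <= self.nucleus_axis_max:
            raise ValueError("invalid nucleus axis range")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if not 0.0 <= self.illumination_gradient <= 0.3:
            raise ValueError("illumination gradient amplitude must be in [0, 0.3]")
        if self.noise_sigma < 0 or self.blur_sigma < 0:
            raise ValueError("degradation parameters must be non-negative")
        hi_nucleus = self.nucleus_intensity + self.nucleus_jitter
        lo_cyto = self.cytoplasm_intensity - self.cytoplasm_jitter
        hi_cyto = self.cytoplasm_intensity + self.cytoplasm_jitter
        if not (hi_nucleus < lo_cyto and hi_cyto < self.background_intensity):
            raise ValueError("intensities must satisfy nucleus < cytoplasm < background")


def _ellipse(height: int, width: int, cy: float, cx: float,
             a: float, b: float, theta: float) -> np.ndarray:
    """Boolean raster of a rotated ellipse with semi-axes a, b."""
    yy, xx = np.mgrid[0:height, 0:width]
    dy = yy - cy
    dx = xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _place_centers(spec: SceneSpec, axes_max: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample nucleus centers honoring the overlap constraint."""
    margin = spec.cytoplasm_scale * float(axes_max.max()) + 1.0
    lo_y, hi_y = margin, spec.height - margin - 1.0
    lo_x, hi_x = margin, spec.width - margin - 1.0
    if lo_y >= hi_y or lo_x >= hi_x:
        raise ValueError("nuclei too large for the requested image size")
    centers: list[tuple[float, float]] = []
    for k in range(spec.n_nuclei):
        for _ in range(500):
            cy = rng.uniform(lo_y, hi_y)
            cx = rng.uniform(lo_x, hi_x)
            ok = True
            for j, (py, px) in enumerate(centers):
                d_min = (1.0 - spec.overlap_fraction) * (axes_max[k] + axes_max[j] + 4.0)
                if np.hypot(cy - py, cx - px) < d_min:
                    ok = False
                    break
            if ok:
                centers.append((cy, cx))
                break
        else:
            raise ValueError(
                f"could not place nucleus {k + 1}/{spec.n_nuclei} at "
                f"overlap_fraction={spec.overlap_fraction} after 500 attempts"
            )
    return np.array(centers)


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one scene.

    Returns
    -------
    (rgb, mask)
        ``rgb`` is the degraded (H, W, 3) image in [0, 1]; ``mask`` is the
        exact pre-degradation boolean nucleus mask.
    """
    rng = np.random.default_rng(spec.seed)
    axes_a = rng.uniform(spec.nucleus_axis_min, spec.nucleus_axis_max, spec.n_nuclei)
    axes_b = rng.uniform(spec.nucleus_axis_min, spec.nucleus_axis_max, spec.n_nuclei)
    thetas = rng.uniform(0.0, np.pi, spec.n_nuclei)
    axes_max = np.maximum(axes_a, axes_b)
    centers = _place_centers(spec, axes_max, rng)

    value = np.full((spec.height, spec.width), spec.background_intensity)
    cell_region = np.zeros((spec.height, spec.width), dtype=bool)
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    for k in range(spec.n_nuclei):
        cy, cx = centers[k]
        cyto = _ellipse(spec.height, spec.width, cy, cx,
                        spec.cytoplasm_scale * axes_a[k], spec.cytoplasm_scale * axes_b[k],
                        thetas[k])
        cyto_v = spec.cytoplasm_intensity + rng.uniform(-1, 1) * spec.cytoplasm_jitter
        # overlapping cytoplasm keeps the darker (denser) value
        value[cyto] = np.minimum(value[cyto], cyto_v)
        cell_region |= cyto
        nuc = _ellipse(spec.height, spec.width, cy, cx, axes_a[k], axes_b[k], thetas[k])
        nuc_v = spec.nucleus_intensity + rng.uniform(-1, 1) * spec.nucleus_jitter
        value[nuc] = np.minimum(value[nuc], nuc_v)
        mask |= nuc

    hue = np.full_like(value, spec.stain_hue)
    sat = np.where(cell_region, spec.cell_saturation, spec.background_saturation)
    rgb = hsv_to_rgb(np.stack([hue, sat, value], axis=-1))
    rgb = degrade(rgb, spec.illumination_gradient, spec.noise_sigma, spec.blur_sigma, rng)
    return rgb, mask


def degrade(
    img: np.ndarray,
    gradient: float = 0.0,
    noise_sigma: float = 0.0,
    blur_sigma: float = 0.0,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Apply illumination gradient, blur, then noise; zero parameters = identity.

    The gradient is a left-to-right additive ramp of peak-to-peak amplitude
    ``gradient``, symmetric about zero.  The result is clamped to [0, 1]
    whenever any degradation was applied.
    """
    if gradient < 0 or noise_sigma < 0 or blur_sigma < 0:
        raise ValueError("degradation parameters must be non-negative")
    img = np.asarray(img, dtype=np.float64)
    if gradient == 0.0 and noise_sigma == 0.0 and blur_sigma == 0.0:
        return img.copy()
    out = img.copy()
    w = out.shape[1]
    if gradient > 0.0:
        ramp = gradient * (np.arange(w) / (w - 1) - 0.5)
        out = out + (ramp[None, :, None] if out.ndim == 3 else ramp[None, :])
    if blur_sigma > 0.0:
        sigma = (blur_sigma, blur_sigma, 0) if out.ndim == 3 else blur_sigma
        out = ndi.gaussian_filter(out, sigma=sigma, mode="reflect")
    if noise_sigma > 0.0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sigma, out.shape)
    return np.clip(out, 0.0, 1.0)


# difficulty grid cycled by make_fixture_suite: (overlap, noise, gradient)
_DIFFICULTY_GRID = [
    (0.0, 0.00, 0.0),
    (0.0, 0.03, 0.0),
    (0.0, 0.00, 0.1),
    (0.3, 0.00, 0.0),
    (0.0, 0.03, 0.1),
    (0.3, 0.03, 0.0),
    (0.3, 0.00, 0.1),
    (0.3, 0.03, 0.1),
]


def _scene_spec_for(i: int, seed: int, rng: np.random.Generator) -> tuple[SceneSpec, str]:
    overlap, noise, gradient = _DIFFICULTY_GRID[i % len(_DIFFICULTY_GRID)]
    group = "normal" if i % 2 == 0 else "abnormal"
    if group == "normal":  # small, regular nuclei
        axis_min, axis_max, n_nuclei = 4.0, 7.0, 4
    else:  # larger, irregular (eccentric) nuclei, as in dysplastic cells
        axis_min, axis_max, n_nuclei = 6.0, 12.0, 3
    spec = SceneSpec(
        n_nuclei=n_nuclei,
        nucleus_axis_min=axis_min,
        nucleus_axis_max=axis_max,
        overlap_fraction=overlap,
        noise_sigma=noise,
        illumination_gradient=gradient,
        seed=int(rng.integers(2**31 - 1)),
    )
    return spec, group


def make_fixture_suite(out_dir: str | Path, n_images: int, seed: int) -> pd.DataFrame:
    """Write ``n_images`` paired image/mask PNGs spanning a difficulty grid.

    The grid varies overlap x noise x illumination gradient, alternating a
    normal-like (small regular nuclei) and abnormal-like (large irregular
    nuclei) group label.  The returned manifest (also written as
    ``manifest.csv``) stores every ``SceneSpec`` field, so any row can be
    re-fed to :func:`generate_scene` to regenerate its image bitwise.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_images):
        spec, group = _scene_spec_for(i, seed, rng)
        rgb, mask = generate_scene(spec)
        image_name = f"scene_{i:03d}.png"
        mask_name = f"scene_{i:03d}_mask.png"
        image_io.save_image(out_dir / image_name, rgb)
        image_io.save_mask(out_dir / mask_name, mask)
        rows.append({"image": image_name, "mask": mask_name, "group": group, **asdict(spec)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def spec_from_row(row) -> SceneSpec:
    """Rebuild the ``SceneSpec`` of one manifest row (dict or pandas Series)."""
    names = {f.name for f in fields(SceneSpec)}
    kwargs = {k: row[k] for k in names}
    for f in fields(SceneSpec):
        if f.name in ("height", "width", "n_nuclei", "seed"):
            kwargs[f.name] = int(kwargs[f.name])
        else:
            if f.name not in ("stain_hue",) and not isinstance(kwargs[f.name], str):
                kwargs[f.name] = float(kwargs[f.name])
    kwargs["stain_hue"] = float(kwargs["stain_hue"])
    return SceneSpec(**kwargs)
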