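# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations of `nucleoseg`. It states no empirical claim that the
test suite or `scripts/acceptance.py` does not itself compute.

## Pipeline model and assumptions

The pipeline assumes a three-mode intensity structure — dark nuclei, lighter
cytoplasm, bright background — which holds for hematoxylin-stained cervical
cytology under reasonably uniform illumination. Everything downstream
follows from that assumption: the three-class Otsu criterion, the
darkest-class-as-nucleus rule, and the trimodal design of the synthetic
generator. Images violating it (e.g. heavy debris, inverted contrast) are
out of model.

### Color space

HSV conversion uses the hexcone model with hue in degrees [0, 360),
saturation and value in [0, 1]. The inverse goes through chroma `C = V·S`,
intensity adjustment `X = C·(1 − |(H/60) mod 2 − 1|)` and brightness match
`m = V − C`, with the six 60° hue sectors assigning (R′,G′,B′). Conventions:
H = 0 at achromatic pixels, S = 0 where V = 0. All arithmetic is float64 in
[0, 1]; scaling to 8 bits (round half to even, clamp) happens only at file
serialization, so no stage accumulates quantization error. The forward and
inverse maps are exact inverses (tested to 1e−9 over 10⁵ pixels).

### Enhancement

The bilateral filter (window radius r, spatial σ_s, range σ_r) computes a
windowed weighted mean with unnormalized Gaussians; borders are handled by
mirror reflection (`np.pad` "reflect"), avoiding the darkening a zero pad
would cause. Internally it accumulates `Σ w·(I_neighbor − I_center)` and adds
it back to the center, which is algebraically the same weighted mean but
makes constant regions exact fixed points. Defaults σ_s = 3 px, σ_r = 0.1,
r = 6 (= ⌈2σ_s⌉, so the spatial kernel is not truncated early) — common
values for 8-bit micrographs at Herlev-like resolution; all configurable.

The adaptive gamma is driven by the mean of the *filtered* V channel. The
two branch formulas (linear `1 + (0.5 − MI)` for MI > 0.5, hyperbolic
`1/(2·MI)` otherwise) meet at γ = 1 for MI = 0.5. Note the net effect: a
bright image (MI > 0.5) receives γ < 1, which brightens further; a dark
image receives γ > 1, which darkens. Whether this direction or its opposite
is intended is genuinely ambiguous in the method's published description
(its prose labels and its formulas disagree), so the branch-to-formula
mapping is exposed as `gamma.convention`: `equations` (default, the mapping
above) or `prose` (formulas swapped between branches, so dark images get
γ > 1 from the linear rule). Both conventions are continuous at MI = 0.5.
The hyperbolic branch diverges as MI → 0; γ is clamped at `gamma.max`
(default 5.0) with a warning. The power law itself, `V ← V^γ` on [0, 1], is
the universal definition of gamma correction.

### Segmentation

Grayscale is BT.601 luminance (0.299, 0.587, 0.114 — the default of
mainstream imaging stacks; configurable), quantized by `floor(255·v + 0.5)`
for bit-exact histograms. The multi-Otsu search evaluates
σ_B² = Σ_k ω_k (μ_k − μ_T)² for all pairs 0 ≤ t₁ < t₂ ≤ 254 via cumulative
moments (an O(L²) broadcast); empty classes contribute zero. Ties are broken
to the lexicographically smallest (t₁, t₂) so results are deterministic and
agree exactly with exhaustive enumeration (tested on 200 random histograms,
including spiky ones with tie plateaus). The between-class sum runs over the
three defined classes. Histograms with fewer than three occupied levels are
rejected with an explicit error; the batch runner logs and skips such
images.

### Refinement

The post-processing is conditional: each remedy fires only when its trigger
is met, and every decision is recorded.

| step | trigger | tool | default |
|---|---|---|---|
| opening | any component area < A_min | disk radius 2 | A_min = 0.1 % of image area |
| hole filling | interior background region ≥ 10 px | border flood fill, 4-connected background | 10 px |
| closing | jaggedness > 1.15 | disk radius 3 | 1.15 |
| edge refinement | optional, after closing | Canny / Sobel near the boundary | off |
| area filter | always | keep components ≥ A_min | — |

A_min as a fraction of image area is scale-free across varying crop sizes.
The disk radii (2 / 3) smooth at nucleus scale without merging adjacent
nuclei at Herlev-like resolutions. Jaggedness is the area-weighted mean of
component perimeter over convex-hull perimeter (dimensionless,
rotation-invariant); since the discrete perimeter estimator can dip slightly
below the hull perimeter on tiny ragged components, the per-component ratio
is clamped at 1. Hole filling uses 4-connected background to match the
4-connected foreground — deviating from the usual 8/4 duality —
with `background_connectivity: 8` available. Closing pads the image by the
element radius first, so it equals the infinite-plane closing restricted to
the window and stays idempotent for border-touching objects. Note that the
strict Euclidean disk of radius 1 is the 4-neighbor cross; opening with it
clips square corners and closing with it cannot bridge a collinear 1-px gap
(the 3×3 square element does both).

### Baselines

All five binarizers run on integer 0–255 gray levels — the scale their
canonical constants assume — with windows cropped at image borders. Window
sums use int64 integral images of I and I², which makes them *bit-exact*
against direct summation, so the fast path and a naive double-loop reference
produce identical masks (tested per method). Foreground is the dark side
(`I < T`), matching the nucleus convention; `invert` flips it. Constants:
Bradley k = 12 %, Sauvola k = 0.1 with R = 128, Nick k = −0.13 (all from the
methods' standard parameterizations), Niblack k = −0.2 (the method's
canonical value). Nick uses the canonical form
`T = m + k·√((Σ_w I² − m²)/N)`. Feng requires two windows: the primary for
m, s and the local minimum M, a secondary (2× radius) for Rs, the dynamic
range of the standard deviation (max of s over the secondary window); its
coefficients α₁ = 0.12, γ = 2, k₁ = 0.25, k₂ = 0.04 follow the method's
original publication and are not derived from any cytology benchmark. When
Rs = 0 (perfectly flat secondary window) it is replaced by 1, making the
contrast terms vanish. Default window radius 15 px for all methods,
configurable and logged.

### Evaluation

Degenerate-case conventions (empty prediction → precision 1; empty truth and
prediction → recall 1, F1 1; each flagged) keep batch tables numeric while
marking the cases. PSNR compares the original grayscale against the enhanced
grayscale, MAX = 1 on the normalized scale, +inf for identical images.
Aggregation uses the sample (n−1) standard deviation. The paired t-test is
the classical statistic with two-sided p from the t distribution (df = n−1),
α = 0.05; zero-variance differences are reported as degenerate (t = 0, p = 1
when the mean is also zero; t = ±inf, p = 0 otherwise) with flags rather
than NaN.

## Synthetic data: what it emulates and what it does not

The generator emulates: trimodal stain intensities with per-cell jitter,
elliptical nuclei of controllable size/eccentricity inside cytoplasm
ellipses, controllable nucleus overlap (minimum-center-distance rejection
sampling; overlap 0 guarantees ≥ 4 px gaps, hence separate 4-connected
components), purple-magenta stain hue via HSV colorization, left-to-right
linear illumination gradient, Gaussian optics blur, additive Gaussian sensor
noise with post-noise clamping (matching 8-bit saturation). Defaults:
nucleus 0.15 ± 0.05, cytoplasm 0.55 ± 0.05, background 0.85, blur 0.8 px,
noise σ 0.01, 128×128 px — chosen as a realistic but unambiguous rendering
of the stained-cell contrast the pipeline targets.

It does **not** emulate chromatin texture, nucleoli, debris, leukocytes,
mucus, focus variation across the field, or the irregular (non-elliptical)
nucleus outlines of severe dysplasia. Consequently, passing the end-to-end
tests shows the pipeline correctly implements its model and solves the
easy-to-moderate synthetic regime; it does not certify performance on real
Herlev images, which must be evaluated separately with the same `compare`
harness.

The fixture grid (`make_fixture_suite`) crosses overlap {0, 0.3} × noise
{0, 0.03} × gradient {0, 0.1} and alternates a "normal" (4 small regular
nuclei) / "abnormal" (3 large eccentric nuclei) group label for groupwise
aggregation tests. The acceptance script uses 16 grid images at 128×128 —
two full grid cycles, enough for stable means at second-scale runtime.

## Known limitations

* Touching nuclei are not split (no watershed/concavity analysis); at high
  overlap the mask merges them, which the component-count metrics reflect.
* The pipeline is global in its threshold choice; severe illumination
  gradients that overlap the class modes can defeat multi-Otsu even after
  enhancement.
* Baseline constants are text-binarization heritage; their poor precision on
  cell images (whole cells darker than background) is expected behavior, not
  a tuning failure.
* The `prose` gamma convention is provided for completeness; all defaults
  and tests use `equations`.
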