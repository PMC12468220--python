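"""Grayscale conversion, histogram moments, and three-class Otsu search."""

import numpy as np
import pytest
from skimage.filters import threshold_multiotsu

from helpers import exhaustive_multiotsu, random_histogram
from nucleoseg.segmentation import (
    IntensityHistogram,
    ThresholdPair,
    class_stats,
    compute_histogram,
    extract_class_mask,
    multi_otsu,
    quantize_u8,
    to_grayscale,
)


def spike_histogram(levels_weights):
    p = np.zeros(256)
    for level, weight in levels_weights:
        p[level] = weight
    return IntensityHistogram.from_probabilities(p / p.sum())


class TestGrayscale:
    @pytest.mark.parametrize(
        "rgb, level",
        [((1, 1, 1), 255), ((0, 0, 0), 0), ((1, 0, 0), 76), ((0, 1, 0), 150)],
    )
    def test_bt601_levels(self, rgb, level):
        img = np.array([[rgb]], dtype=float)
        assert quantize_u8(to_grayscale(img))[0, 0] == level

    def test_quantization_rule(self):
        # floor(v*255 + 0.5): 0.4/255 stays 0, 0.5/255 rounds up
        vals = np.array([[0.4 / 255, 0.5 / 255, 1.0]])
        np.testing.assert_array_equal(quantize_u8(vals), [[0, 1, 255]])


class TestHistogram:
    def test_constant_image(self):
        h = compute_histogram(np.full((8, 8), 128, dtype=np.uint8))
        assert h.p[128] == 1.0
        assert h.mean == 128.0
        assert h.variance == 0.0

    def test_two_point_distribution(self):
        levels = np.array([[0, 255], [0, 255]], dtype=np.uint8)
        h = compute_histogram(levels)
        assert h.mean == pytest.approx(127.5)
        assert h.variance == pytest.approx(127.5**2)

    def test_normalization(self, rng):
        levels = rng.integers(0, 256, (40, 40)).astype(np.uint8)
        assert compute_histogram(levels).p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_rejects_empty_and_float(self):
        with pytest.raises(ValueError):
            compute_histogram(np.zeros((0, 3), dtype=np.uint8))
        with pytest.raises(ValueError):
            compute_histogram(np.zeros((2, 2)))


class TestClassStats:
    def test_three_equal_spikes(self):
        h = spike_histogram([(10, 1), (128, 1), (240, 1)])
        st = class_stats(h, ThresholdPair(10, 128))
        np.testing.assert_allclose(st.omega, [1 / 3] * 3, atol=1e-12)
        np.testing.assert_allclose(st.mu, [10, 128, 240], atol=1e-12)

    def test_single_level_gives_zero_between_variance(self):
        h = spike_histogram([(100, 1)])
        assert class_stats(h, ThresholdPair(50, 150)).sigma_b == 0.0

    def test_variance_decomposition(self, rng):
        for _ in range(50):
            h = IntensityHistogram.from_probabilities(random_histogram(rng))
            t1, t2 = sorted(rng.choice(255, size=2, replace=False))
            st = class_stats(h, ThresholdPair(int(t1), int(t2)))
            assert st.sigma_b + st.sigma_w == pytest.approx(h.variance, abs=1e-9)

    def test_mixture_mean_identity(self, rng):
        h = IntensityHistogram.from_probabilities(random_histogram(rng, spiky=True))
        st = class_stats(h, ThresholdPair(80, 170))
        assert st.omega.sum() == pytest.approx(1.0, abs=1e-12)
        assert float(st.omega @ st.mu) == pytest.approx(h.mean, abs=1e-9)


class TestMultiOtsu:
    def test_three_spike_tie_break(self):
        h = spike_histogram([(10, 1), (128, 1), (240, 1)])
        assert multi_otsu(h) == (10, 128)

    def test_separated_gaussians_thresholds_between_modes(self, rng):
        samples = np.concatenate([
            rng.normal(40, 5, 30000), rng.normal(130, 5, 30000), rng.normal(220, 5, 30000),
        ])
        levels = np.clip(np.round(samples), 0, 255).astype(np.uint8).reshape(300, 300)
        t = multi_otsu(compute_histogram(levels))
        assert 40 < t.t1 < 130 and 130 < t.t2 < 220

    def test_agrees_with_exhaustive_search(self, rng):
        for i in range(30):
            p = random_histogram(rng, spiky=(i % 2 == 0))
            h = IntensityHistogram.from_probabilities(p)
            if np.count_nonzero(p) < 3:
                continue
            assert tuple(multi_otsu(h)) == exhaustive_multiotsu(p)

    def test_agrees_with_skimage_on_smooth_mixture(self, rng):
        samples = np.concatenate([
            rng.normal(60, 12, 20000), rng.normal(140, 10, 20000), rng.normal(210, 8, 20000),
        ])
        levels = np.clip(np.round(samples), 0, 255).astype(np.uint8).reshape(200, 300)
        t = multi_otsu(compute_histogram(levels))
        ref = threshold_multiotsu(levels, classes=3)
        assert abs(t.t1 - ref[0]) <= 1 and abs(t.t2 - ref[1]) <= 1

    def test_reflection_symmetry(self, rng):
        p = random_histogram(rng, spiky=True)
        h = IntensityHistogram.from_probabilities(p)
        hr = IntensityHistogram.from_probabilities(p[::-1].copy())
        t = multi_otsu(h)
        tr = multi_otsu(hr)
        # reflected problem's optimum maps back to t2 = 254 - t1
        assert {254 - tr.t2, 254 - tr.t1} == {t.t1, t.t2} or (
            class_stats(h, ThresholdPair(254 - tr.t2, 254 - tr.t1)).sigma_b
            == pytest.approx(class_stats(h, t).sigma_b, abs=1e-12)
        )

    def test_optimum_beats_random_pairs(self, rng):
        p = random_histogram(rng)
        h = IntensityHistogram.from_probabilities(p)
        best = class_stats(h, multi_otsu(h)).sigma_b
        for _ in range(200):
            t1, t2 = sorted(rng.choice(255, size=2, replace=False))
            assert class_stats(h, ThresholdPair(int(t1), int(t2))).sigma_b <= best + 1e-12

    def test_rejects_degenerate_histograms(self):
        with pytest.raises(ValueError, match="occupied"):
            multi_otsu(spike_histogram([(5, 1), (200, 1)]))


class TestClassMask:
    def test_darkest_class_selected(self):
        levels = np.array([[0, 100], [200, 0]], dtype=np.uint8)
        mask = extract_class_mask(levels, ThresholdPair(50, 150))
        np.testing.assert_array_equal(mask, [[True, False], [False, True]])

    def test_all_dark_image_fully_masked(self):
        levels = np.zeros((4, 4), dtype=np.uint8)
        assert extract_class_mask(levels, ThresholdPair(10, 20)).all()

    def test_other_class_indices(self):
        levels = np.array([[0, 100, 200]], dtype=np.uint8)
        t = ThresholdPair(50, 150)
        np.testing.assert_array_equal(extract_class_mask(levels, t, 1), [[False, True, False]])
        np.testing.assert_array_equal(extract_class_mask(levels, t, 2), [[False, False, True]])

    def test_invalid_threshold_pair_rejected(self):
        with pytest.raises(ValueError):
            extract_class_mask(np.zeros((2, 2), dtype=np.uint8), ThresholdPair(150, 50))
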