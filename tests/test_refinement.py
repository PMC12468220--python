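"""Connected components, morphology, and the conditional refinement flowchart."""

import numpy as np
import pytest
from skimage.morphology import disk

from helpers import flood_fill_labels
from nucleoseg.refinement import (
    RefinementConfig,
    StructuringElement,
    fill_holes,
    filter_by_area,
    jaggedness,
    label_components,
    morphological_close,
    morphological_open,
    postprocess,
    refine_edges,
)

SE1 = StructuringElement("disk", 1)


def place(shape, footprint, at):
    out = np.zeros(shape, dtype=bool)
    r = footprint.shape[0] // 2
    out[at[0] - r : at[0] + r + 1, at[1] - r : at[1] + r + 1] = footprint.astype(bool)
    return out


def annulus(shape=(32, 32), center=(16, 16), r_out=8, r_in=4):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    return (d2 <= r_out**2) & (d2 > r_in**2)


class TestLabeling:
    def test_diagonal_pixels_are_two_components(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(label_components(mask).components) == 2

    def test_plus_sign_single_component_area_five(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 1:4] = True
        mask[1:4, 2] = True
        cs = label_components(mask)
        assert len(cs.components) == 1
        assert cs.components[0].area == 5

    def test_empty_mask(self):
        assert label_components(np.zeros((3, 3), dtype=bool)).components == ()

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(20):
            mask = rng.random((64, 64)) < 0.45
            mine = label_components(mask).label_map
            ref = flood_fill_labels(mask)
            # same partition up to label renaming: identical support and
            # one-to-one label correspondence
            assert np.array_equal(mine > 0, ref > 0)
            pairs = {(a, b) for a, b in zip(mine[mask], ref[mask])}
            assert len(pairs) == len({a for a, _ in pairs}) == len({b for _, b in pairs})


class TestMorphology:
    def test_opening_removes_isolated_pixel(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        assert not morphological_open(mask, SE1).any()

    def test_opening_with_cross_disk_clips_square_corners(self):
        # the Euclidean disk of radius 1 is the 4-neighbor cross: opening a
        # solid square removes exactly its four corner pixels (set-operation
        # oracle: erosion -> 7x7, dilation -> 9x9 minus corners)
        mask = np.zeros((13, 13), dtype=bool)
        mask[2:11, 2:11] = True
        expected = mask.copy()
        for y, x in ((2, 2), (2, 10), (10, 2), (10, 10)):
            expected[y, x] = False
        np.testing.assert_array_equal(morphological_open(mask, SE1), expected)

    def test_opening_with_square_element_preserves_square(self):
        mask = np.zeros((13, 13), dtype=bool)
        mask[2:11, 2:11] = True
        se = StructuringElement("square", 1)
        np.testing.assert_array_equal(morphological_open(mask, se), mask)

    def test_closing_bridges_one_pixel_gap(self):
        mask = np.zeros((7, 9), dtype=bool)
        mask[3, 1:4] = True
        mask[3, 5:8] = True
        closed = morphological_close(mask, StructuringElement("square", 1))
        assert closed[3, 4]

    def test_open_close_idempotent_and_ordered(self, random_masks):
        se = StructuringElement("disk", 2)
        for mask in random_masks:
            opened = morphological_open(mask, se)
            closed = morphological_close(mask, se)
            np.testing.assert_array_equal(morphological_open(opened, se), opened)
            np.testing.assert_array_equal(morphological_close(closed, se), closed)
            assert not (opened & ~mask).any()  # open(x) <= x
            assert not (mask & ~closed).any()  # x <= close(x)

    def test_close_empty_mask(self):
        empty = np.zeros((5, 5), dtype=bool)
        assert not morphological_close(empty, SE1).any()


class TestHoleFilling:
    def test_annulus_becomes_disk(self):
        ring = annulus()
        yy, xx = np.mgrid[0:32, 0:32]
        solid = (yy - 16) ** 2 + (xx - 16) ** 2 <= 64
        np.testing.assert_array_equal(fill_holes(ring), solid)

    def test_solid_square_unchanged(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:6, 2:6] = True
        np.testing.assert_array_equal(fill_holes(mask), mask)

    def test_border_open_cavity_not_filled(self):
        # C-shape whose cavity opens to the top border
        mask = np.zeros((8, 8), dtype=bool)
        mask[0:6, 1] = True
        mask[0:6, 5] = True
        mask[5, 1:6] = True
        np.testing.assert_array_equal(fill_holes(mask), mask)

    def test_extensive(self, random_masks):
        for mask in random_masks:
            assert not (mask & ~fill_holes(mask)).any()


class TestJaggedness:
    def test_square_is_smooth(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[4:16, 4:16] = True
        assert jaggedness(mask) == pytest.approx(1.0, rel=0.02)

    def test_plus_sign_is_jagged(self):
        mask = np.zeros((21, 21), dtype=bool)
        mask[9:12, 1:20] = True
        mask[1:20, 9:12] = True
        assert jaggedness(mask) > 1.15

    def test_never_meaningfully_below_one(self, random_masks):
        for mask in random_masks:
            if mask.any():
                assert jaggedness(mask) > 1.0 - 0.05

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            jaggedness(np.zeros((4, 4), dtype=bool))


class TestEdgeRefinement:
    def test_constant_gray_changes_nothing(self):
        mask = place((16, 16), disk(4), (8, 8))
        gray = np.full((16, 16), 0.5)
        for method in ("canny", "sobel"):
            np.testing.assert_array_equal(refine_edges(mask, gray, method), mask)

    def test_far_pixels_never_modified(self, rng):
        mask = place((32, 32), disk(5), (16, 16))
        gray = rng.random((32, 32))
        out = refine_edges(mask, gray, "sobel")
        from scipy import ndimage as ndi

        near = ndi.binary_dilation(mask ^ ndi.binary_erosion(mask), iterations=3)
        changed = out ^ mask
        assert not (changed & ~near).any()

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            refine_edges(np.ones((4, 4), dtype=bool), np.zeros((4, 4)), "laplacian")


class TestAreaFilter:
    def test_small_component_removed(self):
        mask = np.zeros((16, 32), dtype=bool)
        mask[2:4, 2:5] = True  # area 6
        mask[6:13, 10:20] = True  # area 70
        out = filter_by_area(mask, 10)
        assert out.sum() == 70

    def test_amin_one_is_identity(self, random_masks):
        for mask in random_masks:
            np.testing.assert_array_equal(filter_by_area(mask, 1), mask)

    def test_all_below_threshold_empties_mask(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[1, 1] = mask[5, 6] = True
        assert not filter_by_area(mask, 2).any()

    def test_monotone_in_amin(self, rng):
        mask = rng.random((48, 48)) < 0.4
        prev = filter_by_area(mask, 1)
        for a_min in (2, 4, 8, 16):
            cur = filter_by_area(mask, a_min)
            assert not (cur & ~prev).any()
            prev = cur


class TestPostprocess:
    def test_clean_mask_passes_through(self):
        mask = place((40, 40), disk(8), (20, 20))
        cfg = RefinementConfig(a_min=20)
        result = postprocess(mask, np.full((40, 40), 0.5), cfg)
        np.testing.assert_array_equal(result.mask, mask)
        assert not any(result.fired.values())

    def test_speckles_removed_disk_intact(self):
        mask = place((48, 48), disk(8), (24, 24))
        speckles = [(4, 4), (4, 40), (40, 6)]
        for y, x in speckles:
            mask[y : y + 1, x : x + 2] = True  # area-2 speckles
        cfg = RefinementConfig(a_min=20)
        result = postprocess(mask, np.full((48, 48), 0.5), cfg)
        assert result.fired["opening"]
        disk_px = place((48, 48), disk(8), (24, 24))
        assert not (result.mask & ~disk_px).any()
        assert (result.mask & disk_px).sum() >= 0.95 * disk_px.sum()
        assert result.components_after == 1

    def test_annulus_and_speckles_become_solid_disk(self):
        mask = annulus((48, 48), (24, 24), 10, 5)
        mask[2, 2:4] = True
        cfg = RefinementConfig(a_min=20)
        result = postprocess(mask, np.full((48, 48), 0.5), cfg)
        assert result.fired["opening"] and result.fired["fill_holes"]
        yy, xx = np.mgrid[0:48, 0:48]
        solid = (yy - 24) ** 2 + (xx - 24) ** 2 <= 100
        # opening trims at most the outer boundary; the hole must be gone
        assert result.components_after == 1
        filled_fraction = (result.mask & solid).sum() / solid.sum()
        assert filled_fraction > 0.9
        holes_left = solid & ~result.mask
        assert holes_left.sum() < 0.1 * solid.sum()

    def test_locality_bound(self, rng):
        mask = rng.random((64, 64)) < 0.35
        cfg = RefinementConfig(a_min=5)
        result = postprocess(mask, rng.random((64, 64)), cfg)
        from scipy import ndimage as ndi

        allowed = ndi.binary_dilation(
            mask, structure=disk(1).astype(bool), iterations=cfg.se_close.radius + 3
        )
        assert not (result.mask & ~allowed).any()
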