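"""Despeckling, background removal, feature detection, object labeling."""

import numpy as np
import pytest

from fruitpheno.color_model import ChannelInterval, ThresholdSpec
from fruitpheno.preprocess import exclusion_mask
from fruitpheno.segment import (
    despeckle,
    detect_feature,
    label_objects,
    remove_background,
)
from fruitpheno.synthetic import default_scene, render_scene, scene_analysis_config


# --- independent oracles ---------------------------------------------------


def _disk_offsets(radius):
    return [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]


def opening_oracle(mask, radius):
    """Brute-force erosion-then-dilation with a disc, pixel by pixel."""
    offsets = _disk_offsets(radius)
    h, w = mask.shape
    eroded = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            eroded[i, j] = all(
                0 <= i + dy < h and 0 <= j + dx < w and mask[i + dy, j + dx]
                for dy, dx in offsets
            )
    dilated = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            dilated[i, j] = any(
                0 <= i + dy < h and 0 <= j + dx < w and eroded[i + dy, j + dx]
                for dy, dx in offsets
            )
    return dilated


def flood_fill_count(mask):
    """8-connected component count via explicit stack-based flood fill."""
    mask = mask.copy()
    h, w = mask.shape
    count = 0
    for si in range(h):
        for sj in range(w):
            if not mask[si, sj]:
                continue
            count += 1
            stack = [(si, sj)]
            mask[si, sj] = False
            while stack:
                i, j = stack.pop()
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ni, nj = i + di, j + dj
                        if 0 <= ni < h and 0 <= nj < w and mask[ni, nj]:
                            mask[ni, nj] = False
                            stack.append((ni, nj))
    return count


# --- despeckle -------------------------------------------------------------


class TestDespeckle:
    def test_isolated_pixel_removed_block_kept(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[3, 3] = True
        mask[10:20, 10:20] = True
        out = despeckle(mask, 2)
        assert not out[3, 3]
        assert out[12:18, 12:18].all()  # block bulk retained
        np.testing.assert_array_equal(out, opening_oracle(mask, 2))

    def test_radius_zero_identity(self, rng):
        mask = rng.random((20, 20)) < 0.4
        np.testing.assert_array_equal(despeckle(mask, 0), mask)

    def test_idempotent(self, rng):
        mask = rng.random((40, 40)) < 0.5
        once = despeckle(mask, 2)
        np.testing.assert_array_equal(despeckle(once, 2), once)

    def test_anti_extensive(self, rng):
        for _ in range(5):
            mask = rng.random((30, 30)) < 0.5
            out = despeckle(mask, 1)
            assert not (out & ~mask).any()

    @pytest.mark.parametrize("radius", [1, 2, 3])
    def test_matches_brute_force_oracle(self, rng, radius):
        for density in (0.3, 0.5, 0.7):
            mask = rng.random((24, 24)) < density
            np.testing.assert_array_equal(despeckle(mask, radius), opening_oracle(mask, radius))

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            despeckle(np.zeros((4, 4), dtype=bool), -1)


# --- labeling --------------------------------------------------------------


class TestLabelObjects:
    def test_two_blocks(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[5:25, 5:25] = True
        mask[35:55, 35:55] = True
        out = label_objects(mask, min_object_area=10)
        assert out.n_objects == 2
        assert out.pixel_counts == {1: 400, 2: 400}
        assert out.bboxes[1] == (5, 5, 24, 24)

    def test_minimum_area_boundary(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:5, 2:5] = True  # 9 pixels
        assert label_objects(mask, min_object_area=10).n_objects == 0
        assert label_objects(mask, min_object_area=9).n_objects == 1

    def test_labels_ordered_row_major(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[10:14, 1:5] = True  # lower-left, later in row-major order
        mask[1:5, 10:14] = True  # upper-right, first
        out = label_objects(mask, min_object_area=1)
        assert out.bboxes[1] == (1, 10, 4, 13)
        assert out.bboxes[2] == (10, 1, 13, 4)

    def test_component_count_matches_flood_fill_oracle(self, rng):
        for density in (0.2, 0.4, 0.6):
            mask = rng.random((64, 64)) < density
            out = label_objects(mask, min_object_area=1)
            assert out.n_objects == flood_fill_count(mask)

    def test_diagonal_touch_is_one_object(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        assert label_objects(mask).n_objects == 1


# --- background removal and feature detection ------------------------------


@pytest.fixture(scope="module")
def scene():
    spec = default_scene(seed=5, reverted_fraction=0.3, n_specks=0, anti_alias=False)
    img, truth = render_scene(spec)
    return spec, img, truth


BG_SPEC = ThresholdSpec((ChannelInterval("a", lo=-10.0),))
RDR_SPEC = ThresholdSpec((ChannelInterval("a", lo=16.15),))


class TestRemoveBackground:
    def test_recovers_exact_berry_pixels(self, scene):
        spec, img, truth = scene
        excl = exclusion_mask(img.shape, scene_analysis_config(spec).exclude_region)
        fruit = remove_background(img.pixels, BG_SPEC, despeckle_radius=0, exclusion=excl)
        expected = np.zeros(img.shape, dtype=bool)
        for m in truth.berry_masks:
            expected |= m
        np.testing.assert_array_equal(fruit, expected)

    def test_all_background_image_yields_empty_mask(self):
        img = np.full((30, 30, 3), (60, 120, 60), dtype=np.uint8)
        assert not remove_background(img, BG_SPEC, despeckle_radius=0).any()

    def test_specks_removed_by_despeckling(self):
        spec = default_scene(seed=5, reverted_fraction=0.3, n_specks=5, anti_alias=False)
        img, truth = render_scene(spec)
        excl = exclusion_mask(img.shape, scene_analysis_config(spec).exclude_region)
        raw = remove_background(img.pixels, BG_SPEC, despeckle_radius=0, exclusion=excl)
        clean = remove_background(img.pixels, BG_SPEC, despeckle_radius=2, exclusion=excl)
        union = np.zeros(img.shape, dtype=bool)
        for m in truth.berry_masks:
            union |= m
        assert (raw & ~union).any()  # specks present before despeckling
        assert not (clean & ~union).any()  # gone after


class TestDetectFeature:
    def test_feature_is_subset_of_fruit(self, scene, rng):
        _, img, _ = scene
        fruit = remove_background(img.pixels, BG_SPEC, despeckle_radius=2)
        feature = detect_feature(img.pixels, fruit, RDR_SPEC, despeckle_radius=2)
        assert not (feature & ~fruit).any()

    def test_recovers_exact_reverted_pixels(self, scene):
        _, img, truth = scene
        fruit = remove_background(img.pixels, BG_SPEC, despeckle_radius=0)
        feature = detect_feature(img.pixels, fruit, RDR_SPEC, despeckle_radius=0)
        # fruit here still contains the (unexcluded) reference bar, but the
        # bar is not reverted-colored, so the feature count is exact
        assert int(feature.sum()) == truth.n_reverted_pixels

    def test_rejecting_spec_gives_empty_mask(self, scene):
        _, img, _ = scene
        fruit = remove_background(img.pixels, BG_SPEC, despeckle_radius=0)
        nothing = ThresholdSpec((ChannelInterval("L", lo=99.9),))
        assert not detect_feature(img.pixels, fruit, nothing, 0).any()

    def test_feature_spec_equal_to_background_spec_gives_full_fruit(self, scene):
        _, img, _ = scene
        fruit = remove_background(img.pixels, BG_SPEC, despeckle_radius=0)
        feature = detect_feature(img.pixels, fruit, BG_SPEC, despeckle_radius=0)
        np.testing.assert_array_equal(feature, fruit)
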