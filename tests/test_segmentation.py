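"""Segmentation stages against brute-force oracles and nesting invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from puncta_ml.errors import ConfigError
from puncta_ml.image_io import PixelScale
from puncta_ml.segmentation import (
    LabelImage,
    SegmentationConfig,
    background_filter,
    dilate_mask,
    flatten_thresholds,
    label_components,
    multi_threshold,
    prefilter,
    size_filter,
    watershed_split,
)
from conftest import gaussian_spot


def naive_median3(image):
    """Brute-force 3x3 median with reflective borders."""
    padded = np.pad(image, 1, mode="symmetric")  # edge-duplicating reflection
    out = np.empty_like(image, dtype=float)
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            out[r, c] = np.median(padded[r : r + 3, c : c + 3])
    return out


def naive_dilate(mask, radius):
    """Pixelwise OR of disk-translates of the mask."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    offsets = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]
    for r, c in zip(*np.nonzero(mask)):
        for dr, dc in offsets:
            if 0 <= r + dr < h and 0 <= c + dc < w:
                out[r + dr, c + dc] = True
    return out


class TestPrefilter:
    def test_disabled_is_identity_and_uniform_unchanged(self):
        rng = np.random.default_rng(1)
        img = rng.random((12, 12))
        np.testing.assert_array_equal(prefilter(img, enabled=False), img)
        flat = np.full((8, 8), 0.4)
        np.testing.assert_allclose(prefilter(flat, enabled=True), flat)

    def test_salt_pixel_removed_matches_naive_median(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        out = prefilter(img, enabled=True)
        assert out[4, 4] == 0.0
        np.testing.assert_allclose(out, naive_median3(img))

    def test_matches_naive_median_on_random_image(self):
        rng = np.random.default_rng(3)
        img = rng.random((15, 11))
        np.testing.assert_allclose(prefilter(img, True), naive_median3(img))


class TestMultiThreshold:
    def test_uniform_images(self):
        cfg = SegmentationConfig()
        masks0 = multi_threshold(np.zeros((5, 5)), cfg)
        assert not any(m.any() for m in masks0.level_masks)
        masks_half = multi_threshold(np.full((5, 5), 0.5), cfg)
        assert masks_half.level_masks[0].all() and masks_half.level_masks[1].all()
        assert not masks_half.level_masks[2].any()  # 0.5 < 220/255

    def test_gaussian_spot_counts_match_elementwise_oracle(self):
        img = gaussian_spot((41, 41), (20, 20), sigma=3.0)
        cfg = SegmentationConfig()
        masks = multi_threshold(img, cfg)
        for mask, t in zip(masks.level_masks, cfg.thresholds):
            assert mask.sum() == np.sum(img > t)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_nesting_invariant_on_random_images(self, seed):
        img = np.random.default_rng(seed).random((16, 16))
        m1, m2, m3 = multi_threshold(img, SegmentationConfig()).level_masks
        assert np.all(m3 <= m2) and np.all(m2 <= m1)

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            SegmentationConfig(thresholds=(0.5, 0.3, 0.9))
        with pytest.raises(ConfigError):
            SegmentationConfig(min_area_um2=7.0, max_area_um2=6.25)


class TestDilateMask:
    def test_radius_zero_identity_and_single_pixel_disk(self):
        rng = np.random.default_rng(5)
        mask = rng.random((10, 10)) > 0.7
        np.testing.assert_array_equal(dilate_mask(mask, 0), mask)
        point = np.zeros((7, 7), dtype=bool)
        point[3, 3] = True
        np.testing.assert_array_equal(dilate_mask(point, 1), naive_dilate(point, 1))

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_random_mask_matches_or_of_translates(self, seed):
        mask = np.random.default_rng(seed).random((32, 32)) > 0.9
        np.testing.assert_array_equal(dilate_mask(mask, 2), naive_dilate(mask, 2))


class TestBackgroundFilter:
    @staticmethod
    def _two_rois():
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[1:3, 1:3] = 1
        labels[6:9, 6:9] = 2
        return LabelImage(labels=labels, provenance={1: 1, 2: 1})

    def test_factor_zero_keeps_rois_with_nonzero_gradient(self):
        li = self._two_rois()
        grad = np.full((10, 10), 0.2)
        out = background_filter(li, grad, 0.0)
        assert out.n_rois == 2

    def test_mean_gradient_threshold_is_strict(self):
        li = self._two_rois()
        grad = np.zeros((10, 10))
        grad[li.labels == 1] = 0.5
        grad[li.labels == 2] = 0.5
        assert background_filter(li, grad, 0.25).n_rois == 2
        assert background_filter(li, grad, 0.75).n_rois == 0
        assert background_filter(li, grad, 0.5).n_rois == 0  # equality fails

    def test_flat_image_removes_everything(self):
        li = self._two_rois()
        assert background_filter(li, np.zeros((10, 10)), 0.0).n_rois == 0

    def test_monotone_in_factor(self):
        rng = np.random.default_rng(11)
        labels = label_components(rng.random((24, 24)) > 0.75)
        grad = rng.random((24, 24))
        counts = [
            background_filter(labels, grad, f).n_rois for f in (0.0, 0.175, 0.25, 0.5, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)


class TestWatershedSplit:
    def test_disabled_gives_connected_components(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:3, 1:3] = True
        mask[6:9, 6:9] = True
        out = watershed_split(mask, np.zeros((10, 10)), enabled=False)
        assert out.n_rois == 2

    def test_merged_gaussian_pair_split_with_one_true_center_each(self):
        img = gaussian_spot((40, 40), (20, 16), 2.0) + gaussian_spot((40, 40), (20, 24), 2.0)
        img = np.clip(img, 0, 1)
        mask = img > 30 / 255  # fused at the lowest threshold
        assert label_components(mask).n_rois == 1
        out = watershed_split(mask, img, enabled=True)
        assert out.n_rois == 2
        assert out.labels[20, 16] != out.labels[20, 24] != 0

    def test_single_smooth_spot_not_split(self):
        img = gaussian_spot((41, 41), (20, 20), 3.0)
        out = watershed_split(img > 0.2, img, enabled=True)
        assert out.n_rois == 1


class TestSizeFilter:
    def test_empty_input(self, confocal_scale):
        empty = LabelImage(labels=np.zeros((5, 5), dtype=np.int32))
        assert size_filter(empty, confocal_scale, 0.16, 6.25).n_rois == 0

    def test_confocal_scale_band(self, confocal_scale):
        labels = np.zeros((30, 30), dtype=np.int32)
        labels[0, :10] = 1          # 10 px = 0.0984 um^2: below 0.16
        labels[5:15, 5:15] = 2      # 100 px = 0.984 um^2: in band
        li = LabelImage(labels=labels, provenance={1: 1, 2: 1})
        out = size_filter(li, confocal_scale, 0.16, 6.25)
        assert out.n_rois == 1
        assert (out.labels[5:15, 5:15] == 1).all()

    def test_surviving_areas_inside_band(self, unit_scale):
        rng = np.random.default_rng(13)
        li = label_components(rng.random((40, 40)) > 0.6)
        out = size_filter(li, unit_scale, 2.0, 30.0)
        for k in out.roi_ids():
            assert 2.0 <= (out.labels == k).sum() <= 30.0


class TestFlattenThresholds:
    def test_single_level_identity_relabeling(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[1:3, 1:3] = 1
        labels[5:7, 5:7] = 2
        out = flatten_thresholds([LabelImage(labels=labels, provenance={1: 1, 2: 1})])
        assert out.n_rois == 2

    def test_nested_traces_resolved_to_highest_level(self):
        shape = (12, 12)
        l1 = np.zeros(shape, dtype=np.int32)
        l1[2:9, 2:9] = 1
        l2 = np.zeros(shape, dtype=np.int32)
        l2[4:8, 4:8] = 1
        l3 = np.zeros(shape, dtype=np.int32)
        l3[5:7, 5:7] = 1
        out = flatten_thresholds([
            LabelImage(labels=l1, provenance={1: 1}),
            LabelImage(labels=l2, provenance={1: 2}),
            LabelImage(labels=l3, provenance={1: 3}),
        ])
        assert out.n_rois == 1
        assert out.provenance[1] == 3

    def test_disjoint_objects_keep_their_levels(self):
        shape = (12, 20)
        l1 = np.zeros(shape, dtype=np.int32)
        l1[2:5, 2:5] = 1      # seen only at level 1
        l1[2:6, 12:17] = 2    # also seen at levels 2 and 3
        l2 = np.zeros(shape, dtype=np.int32)
        l2[3:5, 13:16] = 1
        l3 = np.zeros(shape, dtype=np.int32)
        l3[3:4, 14:15] = 1
        out = flatten_thresholds([
            LabelImage(labels=l1, provenance={1: 1, 2: 1}),
            LabelImage(labels=l2, provenance={1: 2}),
            LabelImage(labels=l3, provenance={1: 3}),
        ])
        assert out.n_rois == 2
        assert sorted(out.provenance.values()) == [1, 3]
        # brute-force overlap: the kept pair must be pixel-disjoint
        for a in out.roi_ids():
            for b in out.roi_ids():
                if a < b:
                    assert not ((out.labels == a) & (out.labels == b)).any()

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_conservation_on_random_levels(self, seed):
        rng = np.random.default_rng(seed)
        per_level = []
        for level in (1, 2, 3):
            li = label_components(rng.random((20, 20)) > 0.8, level=level)
            per_level.append(li)
        out = flatten_thresholds(per_level)
        assert out.n_rois <= sum(li.n_rois for li in per_level)
        # contiguous relabeling
        present = np.unique(out.labels)
        assert present[-1] == out.n_rois if out.n_rois else present.size == 1
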