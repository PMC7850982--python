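"""HSV classification rules, histogram stretch, and mask post-processing."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.color import hsv2rgb

import uvcollagen as uv
from uvcollagen.core import ClassCutoff, StructureLabel


def image_from_hsv(hsv_pixels, px=1.0):
    """Build an RGBImage whose pixels have the given HSV coordinates."""
    hsv = np.asarray(hsv_pixels, dtype=np.float64).reshape(1, -1, 3)
    return uv.RGBImage(hsv2rgb(hsv), px)


class TestStretchHistogram:
    def test_full_range_input_unchanged_at_0_100(self):
        rng = np.random.default_rng(0)
        pixels = rng.random((32, 32, 3))
        pixels[0, 0] = 0.0
        pixels[0, 1] = 1.0
        img = uv.RGBImage(pixels, 1.0)
        out = uv.stretch_histogram(img, 0, 100)
        np.testing.assert_allclose(out.pixels, pixels, atol=1e-12)

    def test_affine_stretch_of_compressed_channel(self):
        rng = np.random.default_rng(1)
        pixels = 0.25 + 0.5 * rng.random((32, 32, 3))
        pixels[0, 0] = 0.25
        pixels[0, 1] = 0.75
        out = uv.stretch_histogram(uv.RGBImage(pixels, 1.0), 0, 100)
        assert out.pixels.min() == pytest.approx(0.0, abs=1e-12)
        assert out.pixels.max() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(out.pixels, (pixels - 0.25) / 0.5, atol=1e-12)

    def test_values_below_low_percentile_clip_to_zero(self):
        rng = np.random.default_rng(2)
        pixels = rng.random((64, 64, 3))
        out = uv.stretch_histogram(uv.RGBImage(pixels, 1.0), 5, 95)
        for c in range(3):
            lo = np.percentile(pixels[..., c], 5)
            below = pixels[..., c] < lo
            assert (out.pixels[..., c][below] == 0.0).all()

    def test_constant_channel_left_unchanged(self):
        pixels = np.zeros((8, 8, 3))
        pixels[..., 0] = 0.5
        out = uv.stretch_histogram(uv.RGBImage(pixels, 1.0), 1, 99)
        np.testing.assert_array_equal(out.pixels[..., 0], 0.5)

    def test_bad_percentiles_rejected(self):
        img = uv.RGBImage(np.zeros((4, 4, 3)), 1.0)
        with pytest.raises(ValueError):
            uv.stretch_histogram(img, 60, 40)


class TestClassifyHsv:
    @pytest.mark.parametrize(
        "hsv,expected",
        [
            ((0.60, 0.50, 0.80), StructureLabel.NUCLEI),
            ((0.20, 0.50, 0.60), StructureLabel.COLLAGEN),
            ((0.05, 0.60, 0.20), StructureLabel.VACUOLE),
            ((0.50, 0.50, 0.30), StructureLabel.CYTOPLASM),  # fails all boxes
        ],
    )
    def test_rule_boxes(self, hsv, expected):
        img = image_from_hsv([hsv])
        labels = uv.classify_hsv(img)
        assert StructureLabel(labels.labels[0, 0]) == expected

    def test_nuclei_priority_in_hue_overlap(self):
        # h in (0.449, 0.464) with v > 0.656 satisfies both the nuclei
        # and the (wrapped) collagen rule; priority gives nuclei
        img = image_from_hsv([(0.455, 0.5, 0.8)])
        labels = uv.classify_hsv(img)
        assert StructureLabel(labels.labels[0, 0]) == StructureLabel.NUCLEI

    def test_collagen_wraparound_hue(self):
        img = image_from_hsv([(0.90, 0.5, 0.6)])  # h > 0.750 branch
        labels = uv.classify_hsv(img)
        assert StructureLabel(labels.labels[0, 0]) == StructureLabel.COLLAGEN

    def test_partition_invariant(self, small_phantom):
        img, _ = small_phantom
        labels = uv.classify_hsv(img)
        counts = labels.class_counts()
        assert sum(counts.values()) == img.shape[0] * img.shape[1]

    def test_classification_commutes_with_geometric_transposition(self, small_phantom):
        # per-pixel rule: transposing the image transposes the labels
        img, _ = small_phantom
        labels = uv.classify_hsv(img)
        transposed = uv.RGBImage(np.transpose(img.pixels, (1, 0, 2)), img.pixel_size_um)
        labels_t = uv.classify_hsv(transposed)
        np.testing.assert_array_equal(labels_t.labels, labels.labels.T)

    def test_noise_free_phantom_matches_truth(self, clean_phantom):
        img, truth = clean_phantom
        labels = uv.classify_hsv(img)
        for lab in StructureLabel:
            t, p = truth.label_map.mask(lab), labels.mask(lab)
            union = (t | p).sum()
            if union == 0:
                continue
            assert (t & p).sum() / union >= 0.9


class TestReassignSmallRegions:
    def blob_map(self, n_pixels):
        labels = np.zeros((64, 64), dtype=np.uint8)
        flat = np.zeros(64 * 64, dtype=bool)
        # a compact square-ish blob of exactly n_pixels, 8-connected
        side = int(np.ceil(np.sqrt(n_pixels)))
        blob = np.zeros((side, side), dtype=bool)
        blob.flat[:n_pixels] = True
        labels[2 : 2 + side, 2 : 2 + side][blob] = int(StructureLabel.NUCLEI)
        return uv.StructureLabelMap(labels)

    def test_199_pixel_region_reassigned(self):
        out = uv.reassign_small_regions(self.blob_map(199), 200)
        assert (out.labels == int(StructureLabel.CYTOPLASM)).all()

    def test_200_pixel_region_retained(self):
        out = uv.reassign_small_regions(self.blob_map(200), 200)
        assert (out.labels == int(StructureLabel.NUCLEI)).sum() == 200

    def test_zero_threshold_is_identity(self, small_phantom):
        img, _ = small_phantom
        labels = uv.classify_hsv(img)
        out = uv.reassign_small_regions(labels, 0)
        np.testing.assert_array_equal(out.labels, labels.labels)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        labels = uv.StructureLabelMap(rng.integers(0, 4, size=(48, 48)).astype(np.uint8))
        once = uv.reassign_small_regions(labels, 30)
        twice = uv.reassign_small_regions(once, 30)
        np.testing.assert_array_equal(once.labels, twice.labels)


class TestFillCollagenHoles:
    def ribbon_with_hole(self, touch_border=False):
        labels = np.zeros((64, 64), dtype=np.uint8)
        labels[10:50, 5:60] = int(StructureLabel.COLLAGEN)
        if touch_border:
            labels[0:20, 20:30] = int(StructureLabel.CYTOPLASM)
        else:
            labels[25:35, 20:30] = int(StructureLabel.NUCLEI)  # enclosed island
        return uv.StructureLabelMap(labels)

    def test_enclosed_hole_filled(self):
        out = uv.fill_collagen_holes(self.ribbon_with_hole(), 2000)
        assert (out.labels[25:35, 20:30] == int(StructureLabel.COLLAGEN)).all()

    def test_border_touching_region_not_filled(self):
        out = uv.fill_collagen_holes(self.ribbon_with_hole(touch_border=True), 2000)
        assert (out.labels[0:10, 20:30] == int(StructureLabel.CYTOPLASM)).all()

    def test_zero_max_hole_is_identity(self):
        lm = self.ribbon_with_hole()
        out = uv.fill_collagen_holes(lm, 0)
        np.testing.assert_array_equal(out.labels, lm.labels)

    def test_hole_larger_than_bound_not_filled(self):
        out = uv.fill_collagen_holes(self.ribbon_with_hole(), 50)
        assert (out.labels[25:35, 20:30] == int(StructureLabel.NUCLEI)).all()


class TestRedChannelAndNecrosis:
    def test_pure_red_and_green(self):
        red = uv.RGBImage(np.stack([np.ones((4, 4)), np.zeros((4, 4)), np.zeros((4, 4))], -1), 1.0)
        green = uv.RGBImage(np.stack([np.zeros((4, 4)), np.ones((4, 4)), np.zeros((4, 4))], -1), 1.0)
        assert (uv.extract_red_channel(red) == 1.0).all()
        assert (uv.extract_red_channel(green) == 0.0).all()

    def test_vessel_phantom_red_signal(self):
        rng = np.random.default_rng(0)
        pixels = np.clip(rng.normal(0.3, 0.02, (64, 64, 3)), 0, 1)
        vessel = np.zeros((64, 64), dtype=bool)
        vessel[30:34, :] = True
        pixels[vessel] = (0.9, 0.2, 0.2)
        img = uv.RGBImage(pixels, 1.0)
        red = uv.extract_red_channel(img)
        assert red[vessel].mean() > red[~vessel].mean()

    def test_necrosis_requires_cutoffs(self, small_phantom):
        img, _ = small_phantom
        with pytest.raises(ValueError, match="cutoffs"):
            uv.classify_necrosis(img, None)

    def test_degenerate_boxes(self, small_phantom):
        img, _ = small_phantom
        empty = ClassCutoff(h=(0.5, 0.5), s=(0.5, 0.5), v=(0.5, 0.5))
        assert not uv.classify_necrosis(img, empty).any()
        everything = ClassCutoff(h=(0.0, 1.0), s=(0.0, 1.0), v=(0.0, 1.0))
        interior = uv.RGBImage(np.clip(img.pixels, 0.05, 0.95), 1.0)
        # strictly interior HSV coordinates satisfy the full open box
        mask = uv.classify_necrosis(interior, everything)
        assert mask.mean() > 0.99

    def test_painted_orange_patch_recovered(self, clean_phantom):
        img, _ = clean_phantom
        pixels = img.pixels.copy()
        patch = np.zeros(img.shape, dtype=bool)
        patch[40:80, 100:160] = True
        orange = hsv2rgb(np.array([[[0.09, 0.8, 0.9]]]))[0, 0]
        pixels[patch] = orange
        painted = uv.RGBImage(pixels, img.pixel_size_um)
        box = ClassCutoff(h=(0.05, 0.13), s=(0.6, 1.0), v=(0.7, 1.0))
        mask = uv.classify_necrosis(painted, box)
        iou = (mask & patch).sum() / (mask | patch).sum()
        assert iou >= 0.95
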