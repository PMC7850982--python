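"""Fiber decomposition: distance transform, skeleton, strands, measurement."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial import cKDTree

import uvcollagen as uv
from uvcollagen.core import StructureLabel
from uvcollagen.fibers import (
    find_branchpoints,
    measure_strand,
    orientation_of_pixels,
    skeletonize_mask,
    split_strands,
    summarize_fibers,
    thickness_map,
    threshold_thickness,
)
from conftest import collagen_mask_of, match_strands


def brute_force_edt(mask: np.ndarray) -> np.ndarray:
    """Independent oracle: nearest-background distance via a KD-tree over
    explicit background pixel coordinates, frame included."""
    padded = np.pad(np.asarray(mask, bool), 1, constant_values=False)
    bg = np.argwhere(~padded)
    fg = np.argwhere(padded)
    out = np.zeros(padded.shape)
    if len(fg):
        d, _ = cKDTree(bg).query(fg)
        out[fg[:, 0], fg[:, 1]] = d
    return out[1:-1, 1:-1]


def ribbon_mask(h=5, w=40):
    mask = np.zeros((h + 20, w + 20), dtype=bool)
    mask[10 : 10 + h, 10 : 10 + w] = True
    return mask


class TestThicknessMap:
    def test_single_pixel_has_distance_one(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        tmap = thickness_map(mask)
        assert tmap[4, 4] == 1.0
        assert tmap.sum() == 1.0

    def test_ribbon_centerline_distance(self):
        tmap = thickness_map(ribbon_mask())
        center = tmap[12, 15:45]  # center row of the 5-wide ribbon
        assert (center == 3.0).all()

    def test_empty_mask_is_all_zero(self):
        assert thickness_map(np.zeros((8, 8), dtype=bool)).sum() == 0.0

    def test_frame_counts_as_background(self):
        mask = np.ones((5, 5), dtype=bool)
        tmap = thickness_map(mask)
        assert tmap[0, 0] == 1.0
        assert tmap[2, 2] == 3.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        shape = rng.integers(3, 33, size=2)
        mask = rng.random(shape) < rng.uniform(0.2, 0.8)
        np.testing.assert_array_equal(thickness_map(mask), brute_force_edt(mask))


class TestThresholdThickness:
    def test_zero_threshold_keeps_everything(self):
        mask = ribbon_mask()
        tmap = thickness_map(mask)
        np.testing.assert_array_equal(threshold_thickness(tmap, 0.0, 1.0), mask)

    def test_thin_dot_removed_thick_ribbon_kept(self):
        mask = np.zeros((60, 80), dtype=bool)
        mask[10:19, 10:70] = True  # 9-px-wide ribbon: max half-width ~5
        rr, cc = np.ogrid[:60, :80]
        dot = (rr - 45) ** 2 + (cc - 40) ** 2 <= 3**2  # radius-3 dot
        mask |= dot
        tmap = thickness_map(mask)
        out = threshold_thickness(tmap, 8.0, 1.0)  # keep half-width >= 4 px
        assert not out[dot].any()
        assert out[12, 40]

    def test_threshold_above_everything_empties_mask(self):
        tmap = thickness_map(ribbon_mask())
        assert not threshold_thickness(tmap, 100.0, 1.0).any()

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_thickness(np.zeros((4, 4)), -1.0, 1.0)


class TestSkeleton:
    def test_ribbon_skeletonizes_to_center_row_chain(self):
        skel = skeletonize_mask(ribbon_mask())
        rows, cols = np.nonzero(skel)
        assert set(rows) <= {11, 12, 13}  # on/adjacent to the center row
        assert 34 <= len(cols) <= 40
        # 1-px wide: one pixel per column
        assert len(np.unique(cols)) == len(cols)

    def test_one_pixel_line_is_its_own_skeleton(self):
        mask = np.zeros((10, 20), dtype=bool)
        mask[5, 3:17] = True
        np.testing.assert_array_equal(skeletonize_mask(mask), mask)

    def test_empty_mask(self):
        assert not skeletonize_mask(np.zeros((6, 6), dtype=bool)).any()


def plus_skeleton(n=21):
    skel = np.zeros((n, n), dtype=bool)
    mid = n // 2
    skel[mid, :] = True
    skel[:, mid] = True
    return skel


class TestBranchpoints:
    def test_plus_shape_flags_center(self):
        bp = find_branchpoints(plus_skeleton())
        assert (10, 10) in bp
        assert all(abs(r - 10) <= 1 and abs(c - 10) <= 1 for r, c in bp)

    def test_straight_line_has_none(self):
        skel = np.zeros((9, 9), dtype=bool)
        skel[4, 1:8] = True
        assert find_branchpoints(skel) == set()

    def test_y_shape_has_one_branch_region(self):
        skel = np.zeros((15, 15), dtype=bool)
        skel[7, 1:8] = True  # stem
        for i in range(1, 7):
            skel[7 - i, 7 + i] = True  # up arm
            skel[7 + i, 7 + i] = True  # down arm
        bp = find_branchpoints(skel)
        assert len(bp) >= 1
        assert all(abs(r - 7) <= 1 and abs(c - 7) <= 1 for r, c in bp)


class TestSplitStrands:
    def test_plus_splits_into_four(self):
        chains = split_strands(plus_skeleton(), min_strand_px=3)
        assert len(chains) == 4

    def test_straight_line_is_one_strand(self):
        skel = np.zeros((9, 30), dtype=bool)
        skel[4, 2:28] = True
        chains = split_strands(skel)
        assert len(chains) == 1
        assert len(chains[0]) == 26

    def test_disjoint_lines_are_separate_strands(self):
        skel = np.zeros((20, 30), dtype=bool)
        skel[4, 2:28] = True
        skel[14, 2:28] = True
        assert len(split_strands(skel)) == 2

    def test_chain_is_path_ordered(self):
        skel = np.zeros((9, 30), dtype=bool)
        skel[4, 2:28] = True
        chain = split_strands(skel)[0]
        steps = np.abs(np.diff(chain, axis=0))
        assert steps.max() == 1  # consecutive pixels are 8-neighbors

    def test_pixel_accounting_identity(self):
        """Strand pixels + removed branch neighborhoods + dropped short
        chains account for every skeleton pixel."""
        skel = plus_skeleton()
        bp = find_branchpoints(skel)
        chains = split_strands(skel, bp, branch_removal_radius=1, min_strand_px=3)
        from scipy import ndimage
        from skimage.measure import label as cc_label

        bp_mask = np.zeros(skel.shape, dtype=bool)
        for r, c in bp:
            bp_mask[r, c] = True
        removed = ndimage.binary_dilation(bp_mask, np.ones((3, 3), bool)) & skel
        remainder = skel & ~removed
        comps, n = cc_label(remainder, connectivity=2, return_num=True)
        dropped = sum(
            (comps == i).sum() for i in range(1, n + 1) if (comps == i).sum() < 3
        )
        assert sum(len(c) for c in chains) == skel.sum() - removed.sum() - dropped


class TestMeasureStrand:
    def test_ribbon_thickness_estimator_overshoots_by_one(self):
        """Twice the mean centerline distance reads 6 px on a 5-px-wide
        ribbon: the literal doubled-distance estimator carries a +1 px
        bias (distance is to background pixel centers)."""
        mask = ribbon_mask()
        tmap = thickness_map(mask)
        chain = np.column_stack([np.full(30, 12), np.arange(15, 45)])  # true centerline
        rec = measure_strand(chain, tmap, pixel_size_um=1.0)
        assert rec.thickness_um == pytest.approx(6.0, abs=0.01)

    def test_horizontal_chain_orientation_zero(self):
        chain = np.column_stack([np.full(20, 5), np.arange(20)])
        tmap = np.ones((10, 30))
        rec = measure_strand(chain, tmap, 1.0)
        assert rec.orientation_deg == pytest.approx(0.0, abs=1e-9)
        assert rec.length_um == pytest.approx(19.0)

    def test_diagonal_chain_length_and_orientation(self):
        n = 15
        chain = np.column_stack([np.arange(n)[::-1] + 3, np.arange(n) + 2])  # up-right
        tmap = np.ones((30, 30))
        rec = measure_strand(chain, tmap, pixel_size_um=2.0)
        assert rec.length_um == pytest.approx((n - 1) * np.sqrt(2) * 2.0)
        assert rec.orientation_deg == pytest.approx(45.0, abs=1e-9)

    def test_micron_scaling(self):
        chain = np.column_stack([np.full(10, 4), np.arange(10)])
        tmap = np.full((9, 12), 2.0)
        rec = measure_strand(chain, tmap, pixel_size_um=0.5)
        assert rec.thickness_um == pytest.approx(2.0)  # 2*2 px * 0.5 um
        assert rec.length_um == pytest.approx(4.5)

    def test_chain_outside_map_rejected(self):
        chain = np.array([[50, 50]])
        with pytest.raises(ValueError, match="outside"):
            measure_strand(chain, np.zeros((10, 10)), 1.0)


class TestOrientation:
    @pytest.mark.parametrize("angle", [-60.0, -30.0, 0.0, 30.0, 60.0, 90.0])
    def test_synthetic_line_orientations(self, angle):
        t = np.linspace(0, 40, 200)
        rows = 100 - t * np.sin(np.radians(angle))
        cols = 100 + t * np.cos(np.radians(angle))
        pixels = np.unique(np.column_stack([np.round(rows), np.round(cols)]), axis=0)
        got = orientation_of_pixels(pixels)
        diff = abs((got - angle + 90) % 180 - 90)
        assert diff < 2.0


class TestRecoveryOnPhantoms:
    def test_fiber_parameters_recovered(self, slender_phantom):
        _, truth = slender_phantom
        table = uv.analyze_collagen_mask(collagen_mask_of(truth), 1.0)
        tt = truth.fiber_truth
        assert abs(len(table) - len(tt)) <= 0.1 * len(tt)
        matched = match_strands(tt, table)
        o_err = np.abs(((matched.orientation_deg.values - tt.orientation_deg.values) + 90) % 180 - 90)
        assert o_err.mean() <= 5.0
        l_err = np.abs(matched.length_um.values - tt.length_um.values) / tt.length_um.values
        assert l_err.mean() <= 0.10
        t_over = matched.thickness_um.values - tt.thickness_um.values
        assert t_over.mean() <= 2.0 + 0.1 * tt.thickness_um.mean()

    def test_rotation_shifts_recovered_orientation(self):
        from skimage.transform import rotate

        spec = uv.PhantomSpec(
            image_size_px=(512, 512),
            pixel_size_um=1.0,
            n_fibers=15,
            crosslink_probability=0.0,
            fiber_length_um=uv.DistributionSpec(100.0, 20.0),
            fiber_thickness_um=uv.DistributionSpec(6.0, 1.0),
            orientation_deg=uv.DistributionSpec(10.0, 8.0),
            n_nuclei=0,
            n_vacuoles=0,
            noise_sd=0.0,
            rng_seed=12,
        )
        _, truth = uv.generate_phantom(spec)
        mask = collagen_mask_of(truth)
        base = uv.analyze_collagen_mask(mask, 1.0)
        rotated_mask = rotate(mask.astype(float), -30.0, order=0, resize=True) > 0.5
        rot = uv.analyze_collagen_mask(rotated_mask, 1.0)
        # counter-clockwise frame rotation by a degrees adds a to the
        # math-convention orientation; here a = -30
        shift = rot.orientation_deg.mean() - base.orientation_deg.mean()
        assert shift == pytest.approx(-30.0, abs=3.0)


class TestSummarize:
    def test_no_strands_reports_absent_moments(self, clean_phantom):
        _, truth = clean_phantom
        s = summarize_fibers(uv.core.empty_fiber_table(), truth.label_map)
        assert s.n_strands == 0
        assert s.mean_length_um is None
        assert s.collagen_content_pct is not None

    def test_single_strand_has_zero_sd(self):
        from uvcollagen.core import FiberRecord, make_fiber_table

        labels = uv.StructureLabelMap(np.zeros((20, 20), dtype=np.uint8))
        table = make_fiber_table([FiberRecord(0, 10.0, 3.0, 15.0, 11, 5.0, 5.0)])
        s = summarize_fibers(table, labels)
        assert s.n_strands == 1
        assert s.sd_length_um == 0.0

    def test_collagen_content_matches_truth_fraction(self, clean_phantom):
        img, truth = clean_phantom
        labels = uv.classify_hsv(img)
        s = summarize_fibers(uv.core.empty_fiber_table(), labels)
        assert s.collagen_content_pct == pytest.approx(100 * truth.collagen_fraction, abs=2.0)

    def test_necrosis_excluded_from_both_counts(self):
        labels = np.zeros((10, 10), dtype=np.uint8)
        labels[:5, :] = int(StructureLabel.COLLAGEN)
        necro = np.zeros((10, 10), dtype=bool)
        necro[:5, :5] = True  # half of the collagen is necrotic
        lm = uv.StructureLabelMap(labels, necro)
        s = summarize_fibers(uv.core.empty_fiber_table(), lm)
        assert s.collagen_content_pct == pytest.approx(100 * 25 / 75)

    def test_fully_excluded_region_flagged_empty(self):
        lm = uv.StructureLabelMap(np.zeros((4, 4), dtype=np.uint8), np.ones((4, 4), dtype=bool))
        s = summarize_fibers(uv.core.empty_fiber_table(), lm)
        assert s.empty
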