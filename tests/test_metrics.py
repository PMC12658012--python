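import numpy as np
import pytest

from oracles import brute_asd, brute_dice, brute_hd95, brute_surface_points

from fibseg.metrics import (
    asd,
    dice,
    evaluate_pair,
    hd95,
    roi_restrict,
    surface_voxels,
)
from fibseg.volume_io import Mask, ShapeError


def mask(data, spacing=(1, 1, 1)):
    return Mask(np.asarray(data, dtype=np.uint8), spacing)


def box_mask(shape, lo, hi, spacing=(1, 1, 1)):
    data = np.zeros(shape, dtype=np.uint8)
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = 1
    return mask(data, spacing)


class TestDice:
    def test_identical_masks(self):
        m = box_mask((8, 8, 8), (2, 2, 2), (6, 6, 6))
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = box_mask((8, 8, 8), (0, 0, 0), (2, 2, 2))
        b = box_mask((8, 8, 8), (5, 5, 5), (8, 8, 8))
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        # |A| = |B| = 8, |A ∩ B| = 4  ->  2*4 / 16 = 0.5
        a = box_mask((4, 4, 4), (0, 0, 0), (2, 2, 2))
        b = box_mask((4, 4, 4), (0, 0, 1), (2, 2, 3))
        assert a.count() == b.count() == 8
        assert int(np.logical_and(a.data, b.data).sum()) == 4
        assert dice(a, b) == 0.5

    def test_both_empty_is_perfect_agreement(self):
        e = mask(np.zeros((4, 4, 4)))
        assert dice(e, e) == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        a = mask(rng.random((6, 6, 6)) > 0.6)
        b = mask(rng.random((6, 6, 6)) > 0.6)
        assert dice(a, b) == dice(b, a)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            dice(mask(np.zeros((4, 4, 4))), mask(np.zeros((5, 4, 4))))


class TestSurfaceVoxels:
    def test_solid_3cube_shell(self):
        # all voxels except the single 6-connected-interior center voxel
        m = box_mask((5, 5, 5), (1, 1, 1), (4, 4, 4))
        assert len(surface_voxels(m)) == 26

    def test_single_voxel(self):
        data = np.zeros((4, 4, 4), np.uint8)
        data[1, 2, 3] = 1
        pts = surface_voxels(mask(data, (2, 2, 2)))
        np.testing.assert_allclose(pts, [[2.0, 4.0, 6.0]])

    def test_interior_of_5cube_excluded(self):
        m = box_mask((7, 7, 7), (1, 1, 1), (6, 6, 6))
        assert len(surface_voxels(m)) == 125 - 27

    def test_border_voxels_count_outside_as_background(self):
        m = mask(np.ones((3, 3, 3)))
        assert len(surface_voxels(m)) == 26  # only the center is interior


class TestSurfaceDistances:
    def _plates(self, gap_vox=4, spacing=(1, 1, 1)):
        a = np.zeros((10, 6, 6), np.uint8)
        b = np.zeros((10, 6, 6), np.uint8)
        a[2] = 1
        b[2 + gap_vox] = 1
        return mask(a, spacing), mask(b, spacing)

    def test_identical_masks_have_zero_distance(self):
        m = box_mask((8, 8, 8), (2, 2, 2), (6, 6, 6))
        assert asd(m, m) == 0.0
        assert hd95(m, m) == 0.0

    def test_parallel_plates(self):
        a, b = self._plates(gap_vox=4)
        assert asd(a, b) == pytest.approx(4.0)

    def test_spacing_scales_distances(self):
        a1, b1 = self._plates(gap_vox=4, spacing=(1, 1, 1))
        a2, b2 = self._plates(gap_vox=4, spacing=(2, 2, 2))
        assert asd(a2, b2) == pytest.approx(2 * asd(a1, b1))
        assert hd95(a2, b2) == pytest.approx(2 * hd95(a1, b1))

    def test_hd95_below_max_distance(self):
        rng = np.random.default_rng(3)
        a = mask(rng.random((8, 8, 8)) > 0.7)
        b = mask(rng.random((8, 8, 8)) > 0.7)
        from oracles import brute_pooled_distances
        dmax = brute_pooled_distances(a.data, b.data, (1, 1, 1)).max()
        assert hd95(a, b) <= dmax + 1e-12

    def test_empty_side_rejected(self):
        m = box_mask((4, 4, 4), (1, 1, 1), (3, 3, 3))
        with pytest.raises(ValueError):
            asd(m, mask(np.zeros((4, 4, 4))))


class TestOracleEquivalence:
    """Implementation vs all-pairs brute force on random small masks."""

    @pytest.mark.parametrize("seed", range(100))
    def test_asd_hd95_dice_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        spacing = tuple(rng.uniform(0.5, 3.0, 3))
        a = rng.random((8, 8, 8)) > 0.75
        b = rng.random((8, 8, 8)) > 0.75
        if not a.any() or not b.any():
            a[0, 0, 0] = b[7, 7, 7] = True
        ma, mb = mask(a, spacing), mask(b, spacing)
        assert dice(ma, mb) == pytest.approx(brute_dice(a, b), abs=1e-12)
        assert asd(ma, mb) == pytest.approx(brute_asd(a, b, spacing), abs=1e-9)
        assert hd95(ma, mb) == pytest.approx(brute_hd95(a, b, spacing), abs=1e-9)

    def test_surface_definition_matches_brute_force(self):
        rng = np.random.default_rng(42)
        a = rng.random((8, 8, 8)) > 0.6
        a[0, 0, 0] = True
        got = surface_voxels(mask(a, (1.5, 1.0, 2.0)))
        expected = brute_surface_points(a, (1.5, 1.0, 2.0))
        assert len(got) == len(expected)
        got_sorted = got[np.lexsort(got.T)]
        exp_sorted = expected[np.lexsort(expected.T)]
        np.testing.assert_allclose(got_sorted, exp_sorted)


class TestRoiRestrict:
    def _bone(self, z_lo, z_hi, sz=1.0):
        data = np.zeros((8, 8, 400), np.uint8)
        data[3:5, 3:5, z_lo:z_hi + 1] = 1
        return mask(data, (1, 1, sz))

    def test_window_from_gt_extent(self):
        gt = self._bone(0, 350)
        pred = self._bone(0, 350)
        gt_r, pred_r = roi_restrict(gt, pred, 70.0)
        z = np.nonzero(gt_r.data.any(axis=(0, 1)))[0]
        assert z[0] == 70 and z[-1] == 280

    def test_short_bone_gives_empty_roi(self):
        gt = self._bone(100, 240)  # extent exactly 140 mm
        gt_r, _ = roi_restrict(gt, gt, 70.0)
        assert gt_r.count() == 0

    def test_zero_crop_is_identity(self):
        gt = self._bone(10, 390)
        gt_r, pred_r = roi_restrict(gt, gt, 0.0)
        np.testing.assert_array_equal(gt_r.data, gt.data)

    def test_idempotent(self):
        gt = self._bone(0, 350)
        g1, p1 = roi_restrict(gt, gt, 70.0)
        # second application with the same window (derived from original gt)
        g2, p2 = roi_restrict(gt, p1, 70.0)
        np.testing.assert_array_equal(p1.data, p2.data)

    def test_window_applied_to_both_masks(self):
        gt = self._bone(0, 350)
        pred = self._bone(0, 399)
        _, pred_r = roi_restrict(gt, pred, 70.0)
        z = np.nonzero(pred_r.data.any(axis=(0, 1)))[0]
        assert z[0] == 70 and z[-1] == 280


class TestEvaluatePair:
    def test_perfect_prediction(self):
        gt = np.zeros((8, 8, 300), np.uint8)
        gt[3:5, 3:5, 20:280] = 1
        m = mask(gt, (1, 1, 1))
        rep = evaluate_pair(m, m, crop_mm=70.0)
        assert rep.ds == 1.0 and rep.roi_ds == 1.0
        assert rep.asd == 0.0 and rep.hd95 == 0.0
        assert rep.roi_asd == 0.0 and rep.roi_hd95 == 0.0
        assert rep.surface_valid and rep.roi_valid

    def test_end_degradation_helps_roi(self, noiseless_phantom):
        """Deleting the proximal bulge hurts whole-bone Dice more than ROI Dice."""
        gt = noiseless_phantom.left_fibula
        z = np.nonzero(gt.data.any(axis=(0, 1)))[0]
        pred_data = gt.data.copy()
        pred_data[:, :, z[-1] - 8:] = 0  # chop the head region
        pred = Mask(pred_data, gt.spacing, gt.origin)
        crop_mm = 0.15 * (z[-1] - z[0]) * gt.spacing[2]
        rep = evaluate_pair(gt, pred, crop_mm=crop_mm)
        assert rep.roi_ds > rep.ds

    def test_empty_prediction_flagged(self):
        gt = box_mask((8, 8, 200), (3, 3, 10), (5, 5, 190))
        rep = evaluate_pair(gt, mask(np.zeros((8, 8, 200))), crop_mm=10.0)
        assert rep.ds == 0.0
        assert rep.asd is None and rep.hd95 is None
        assert not rep.surface_valid and not rep.roi_valid

    def test_short_gt_invalidates_roi_only(self):
        gt = box_mask((8, 8, 200), (3, 3, 50), (5, 5, 150))  # 100 mm extent
        rep = evaluate_pair(gt, gt, crop_mm=70.0)
        assert rep.ds == 1.0 and rep.surface_valid
        assert not rep.roi_valid and rep.roi_ds is None
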