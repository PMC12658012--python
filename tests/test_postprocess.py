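import numpy as np
import pytest

from oracles import brute_erode_box

from fibseg.postprocess import (
    EmptySurfaceError,
    LabelingError,
    binarize,
    erode,
    extract_mesh,
    keep_largest_components,
    label_left_right,
    mask_to_mesh,
    mesh_volume,
    smooth,
)
from fibseg.preprocess import mirror_lr
from fibseg.volume_io import Mask, Volume


def mask(data, spacing=(1, 1, 1)):
    return Mask(np.asarray(data, np.uint8), spacing)


class TestBinarize:
    def test_threshold_is_inclusive(self):
        v = Volume(np.array([0.4, 0.5, 0.6]).reshape(1, 1, 3), (1, 1, 1))
        np.testing.assert_array_equal(binarize(v, 0.5).data.ravel(), [0, 1, 1])

    def test_extreme_thresholds(self):
        v = Volume(np.random.default_rng(0).random((4, 4, 4)), (1, 1, 1))
        assert binarize(v, 0.0).count() == 64
        assert binarize(v, 1.1).count() == 0

    def test_monotone_in_threshold(self):
        v = Volume(np.random.default_rng(1).random((6, 6, 6)), (1, 1, 1))
        counts = [binarize(v, t).count() for t in (0.2, 0.5, 0.8)]
        assert counts[0] >= counts[1] >= counts[2]


class TestErode:
    def test_cube_erodes_to_center_voxel(self):
        data = np.zeros((5, 5, 5), np.uint8)
        data[1:4, 1:4, 1:4] = 1
        out = erode(mask(data))
        np.testing.assert_array_equal(out.data, brute_erode_box(data))
        assert out.count() == 1 and out.data[2, 2, 2] == 1

    def test_matches_brute_force_on_random_mask(self):
        rng = np.random.default_rng(3)
        data = (rng.random((7, 7, 7)) > 0.35).astype(np.uint8)
        np.testing.assert_array_equal(erode(mask(data)).data, brute_erode_box(data))

    def test_anti_extensive(self, noisy_phantom):
        m = noisy_phantom.left_fibula
        out = erode(m)
        assert not np.logical_and(out.data, ~m.data.astype(bool)).any()

    def test_empty_stays_empty(self):
        assert erode(mask(np.zeros((4, 4, 4)))).count() == 0


class TestSmooth:
    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(0)
        m = mask(rng.random((6, 6, 6)) > 0.5)
        np.testing.assert_array_equal(smooth(m, sigma_mm=0.0).data, m.data.astype(np.float32))

    def test_single_voxel_symmetric_kernel(self):
        data = np.zeros((9, 9, 9), np.uint8)
        data[4, 4, 4] = 1
        f = smooth(mask(data), sigma_vox=1.0).data
        np.testing.assert_allclose(f, f.transpose(1, 0, 2), atol=1e-7)
        np.testing.assert_allclose(f, f.transpose(2, 1, 0), atol=1e-7)

    def test_mass_conserved_for_interior_blob(self):
        data = np.zeros((16, 16, 16), np.uint8)
        data[6:10, 6:10, 6:10] = 1
        f = smooth(mask(data), sigma_vox=1.0).data
        assert f.sum() == pytest.approx(data.sum(), rel=1e-3)
        assert f.min() >= 0.0 and f.max() <= 1.0

    def test_anisotropic_spacing_scales_sigma(self):
        data = np.zeros((9, 9, 9), np.uint8)
        data[4, 4, 4] = 1
        f = smooth(mask(data, spacing=(1, 1, 2)), sigma_mm=2.0).data
        # sigma is 2 voxels along x, 1 voxel along z -> wider spread along x
        assert f[2, 4, 4] > f[4, 4, 2]


class TestExtractMesh:
    def test_cube_volume_recovered(self):
        data = np.zeros((14, 14, 14), np.uint8)
        data[2:12, 2:12, 2:12] = 1  # 10x10x10 voxels at 1 mm
        m = mask(data)
        mesh = extract_mesh(smooth(m, sigma_vox=0.8), iso_level=0.5)
        assert mesh_volume(mesh) == pytest.approx(1000.0, rel=0.10)

    def test_all_zero_field_rejected(self):
        with pytest.raises(EmptySurfaceError):
            extract_mesh(Volume(np.zeros((4, 4, 4)), (1, 1, 1)), 0.5)

    def test_spacing_scales_vertices(self):
        data = np.zeros((10, 10, 10), np.uint8)
        data[3:7, 3:7, 3:7] = 1
        m1 = extract_mesh(smooth(mask(data, (1, 1, 1)), sigma_vox=1.0))
        m2 = extract_mesh(smooth(mask(data, (2, 2, 2)), sigma_vox=1.0))
        np.testing.assert_allclose(m2.vertices, 2.0 * m1.vertices, atol=1e-6)

    def test_watertight_blob(self):
        data = np.zeros((10, 10, 10), np.uint8)
        data[3:7, 3:7, 3:7] = 1
        mesh = extract_mesh(smooth(mask(data), sigma_vox=1.0))
        assert mesh.as_trimesh().is_watertight


class TestKeepLargest:
    def _three_blobs(self):
        data = np.zeros((30, 10, 10), np.uint8)
        data[0:5, 0:5, 0:4] = 1    # 100 voxels
        data[10:15, 0:5, 0:2] = 1  # 50 voxels
        data[20:25, 0:2, 0:1] = 1  # 10 voxels
        return mask(data)

    def test_two_largest_in_descending_order(self):
        comps, shortfall = keep_largest_components(self._three_blobs(), k=2)
        assert not shortfall
        assert [c.count() for c in comps] == [100, 50]

    def test_shortfall_flag_when_too_few(self):
        data = np.zeros((10, 10, 10), np.uint8)
        data[2:5, 2:5, 2:5] = 1
        comps, shortfall = keep_largest_components(mask(data), k=2)
        assert shortfall and len(comps) == 1

    def test_min_fraction_discards_debris(self):
        comps, shortfall = keep_largest_components(self._three_blobs(), k=3,
                                                   min_fraction=0.25)
        assert shortfall  # the 10- and 50-voxel? no: 50 >= 25 -> kept
        assert [c.count() for c in comps] == [100, 50]

    def test_idempotent(self):
        comps, _ = keep_largest_components(self._three_blobs(), k=2)
        merged = mask(comps[0].data | comps[1].data)
        again, _ = keep_largest_components(merged, k=2)
        assert [c.count() for c in again] == [100, 50]

    def test_empty_input(self):
        comps, shortfall = keep_largest_components(mask(np.zeros((4, 4, 4))), k=1)
        assert comps == [] and shortfall

    def test_size_ties_break_by_lateral_centroid(self):
        data = np.zeros((20, 4, 4), np.uint8)
        data[2:4, 0:2, 0:2] = 1
        data[10:12, 0:2, 0:2] = 1
        comps, _ = keep_largest_components(mask(data), k=2)
        assert np.argwhere(comps[0].data)[:, 0].mean() < np.argwhere(comps[1].data)[:, 0].mean()


class TestLabelLeftRight:
    def _pair(self):
        a = np.zeros((144, 8, 8), np.uint8)
        b = np.zeros((144, 8, 8), np.uint8)
        a[28:33, 2:6, 2:6] = 1    # centroid at LR = 30
        b[108:113, 2:6, 2:6] = 1  # centroid at LR = 110
        return mask(a), mask(b)

    def test_greater_lateral_centroid_is_left(self):
        a, b = self._pair()
        out = label_left_right([a, b])
        assert out["left"] is b and out["right"] is a

    def test_order_invariance(self):
        a, b = self._pair()
        out = label_left_right([b, a])
        assert out["left"] is b and out["right"] is a

    def test_mirroring_swaps_labels(self):
        a, b = self._pair()
        out = label_left_right([a, b])
        mirrored = label_left_right([mirror_lr(a), mirror_lr(b)])
        assert mirrored["left"].count() == out["right"].count()
        np.testing.assert_array_equal(mirrored["left"].data, mirror_lr(out["right"]).data)

    def test_ambiguous_centroids_rejected(self):
        a = np.zeros((10, 4, 4), np.uint8)
        a[4:6, 0:2, 0:2] = 1
        with pytest.raises(LabelingError):
            label_left_right([mask(a), mask(a.copy())])


class TestFullChain:
    def test_phantom_fibula_mesh_volume_close_to_mask(self):
        """erode -> smooth -> marching cubes shrinks a tubular bone by about
        one voxel of radius: for a 9 mm tube at 1 mm voxels the box erosion
        alone costs ~25% of the cross-section, so the enclosed mesh volume
        must stay within 35% of the voxel volume (and well above half)."""
        from fibseg.synthetic_ct import PhantomParams, generate_phantom
        p = PhantomParams(grid_shape=(128, 128, 280), spacing=(1.0, 1.0, 1.5),
                          fibula_radius_mm=9.0, fibula_head_radius_mm=11.0,
                          fibula_ankle_radius_mm=10.0, noise_sd=0.0, seed=2)
        m = generate_phantom(p).left_fibula
        mesh = mask_to_mesh(m, erode_iterations=1, sigma_vox=1.0)
        mask_mm3 = m.count() * np.prod(m.spacing)
        assert mesh_volume(mesh) == pytest.approx(mask_mm3, rel=0.35)
        assert mesh_volume(mesh) < mask_mm3  # the chain only shrinks
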