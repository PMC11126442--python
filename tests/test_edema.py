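import numpy as np
import pytest
from scipy.stats import norm

from periomri import ImageVolume
from periomri.edema import (
    DegenerateReferenceError,
    ReferenceStats,
    change_maps,
    classify_edema,
    edema_depth,
    reference_stats,
    refine_partial_volume,
    tooth_max_depth,
)
from periomri.phantom import LesionSpec, PhantomConfig, ToothSite, generate_phantom


def _mask_like(vol, arr):
    return vol.like(np.asarray(arr).astype(np.uint8))


class TestReferenceStats:
    def test_constant_region_is_degenerate(self):
        vol = ImageVolume(np.full((6, 6, 6), 42.0))
        mask = _mask_like(vol, np.ones((6, 6, 6)))
        ref = reference_stats(vol, mask)
        assert ref.mean == 42.0
        assert ref.sd == 0.0
        assert ref.degenerate

    def test_moment_estimator_recovers_gaussian(self):
        rng = np.random.default_rng(8)
        vol = ImageVolume(rng.normal(100, 10, size=(47, 47, 47)))
        mask = _mask_like(vol, np.ones(vol.shape))
        ref = reference_stats(vol, mask)
        assert ref.n_voxels == 47**3
        assert abs(ref.mean - 100) < 0.1
        assert abs(ref.sd - 10) < 0.1

    def test_robust_estimator_resists_contamination(self):
        # 5% of voxels displaced by 10 sigma (symmetric, so the location
        # estimate is not dragged); MAD-based scale stays near truth while
        # the moment SD inflates
        rng = np.random.default_rng(9)
        data = rng.normal(100, 10, size=(40, 40, 40))
        n_out = int(0.05 * data.size)
        flat = data.ravel()
        out_idx = rng.choice(data.size, n_out, replace=False)
        flat[out_idx] += 100.0 * np.where(rng.random(n_out) < 0.5, 1, -1)
        vol = ImageVolume(flat.reshape(data.shape))
        mask = _mask_like(vol, np.ones(vol.shape))
        robust = reference_stats(vol, mask, "robust")
        moment = reference_stats(vol, mask, "moment")
        # contamination oracle: under 5% far outliers the MAD-based scale has
        # expectation 1.4826 * Phi^-1(0.5/0.95/2 + 0.5) * 10 = 10.62
        expected = 1.4826 * norm.ppf(0.5 / 0.95 / 2 + 0.5) * 10.0
        assert robust.sd == pytest.approx(expected, abs=0.3)
        assert moment.sd > 2 * robust.sd  # moment estimator blown up

    def test_tiny_mask_rejected(self):
        vol = ImageVolume(np.zeros((4, 4, 4)))
        mask = _mask_like(vol, np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="2 voxels"):
            reference_stats(vol, mask)


class TestClassifyEdema:
    def test_null_fraction_matches_normal_tail(self, null_phantom):
        """Lesion-free Gaussian marrow: classified fraction equals the
        upper-tail probability beyond 2 SD (0.02275) within 3 binomial SEs."""
        b = null_phantom
        ref = reference_stats(b.stir_t0, b.marrow_ref_mask)
        n_roi = cls = 0
        for roi in b.roi_masks.values():
            e = classify_edema(b.stir_t0, roi, b.bone_mask, ref, k=2)
            n_roi += int((np.asarray(roi.data) > 0).sum())
            cls += int(e.mask.data.sum())
        p = norm.sf(2)
        se = np.sqrt(p * (1 - p) / n_roi)
        assert n_roi >= 1e5
        assert abs(cls / n_roi - p) <= 3 * se

    def test_bright_lesion_interior_fully_classified(self, lesion_phantom):
        from scipy.ndimage import binary_erosion

        b = lesion_phantom
        ref = reference_stats(b.stir_t0, b.marrow_ref_mask)
        e = classify_edema(b.stir_t0, b.bone_mask, b.bone_mask, ref, k=2)
        interior = binary_erosion(np.asarray(b.truth.lesion_mask_t0.data) > 0)
        assert np.all(np.asarray(e.mask.data)[interior] > 0)

    def test_large_k_empties_map(self, lesion_phantom):
        b = lesion_phantom
        ref = reference_stats(b.stir_t0, b.marrow_ref_mask)
        e = classify_edema(b.stir_t0, b.bone_mask, b.bone_mask, ref, k=1e9)
        assert e.mask.data.sum() == 0

    def test_monotone_in_k(self, lesion_phantom):
        b = lesion_phantom
        ref = reference_stats(b.stir_t0, b.marrow_ref_mask)
        prev = None
        for k in (1.0, 2.0, 3.0, 4.0):
            e = classify_edema(b.stir_t0, b.bone_mask, b.bone_mask, ref, k=k)
            cur = np.asarray(e.mask.data) > 0
            if prev is not None:
                assert np.all(cur <= prev)  # mask(k2) subset of mask(k1)
            prev = cur

    def test_degenerate_reference_refused(self, lesion_phantom):
        b = lesion_phantom
        ref = ReferenceStats(mean=100.0, sd=0.0, n_voxels=10)
        with pytest.raises(DegenerateReferenceError):
            classify_edema(b.stir_t0, b.bone_mask, b.bone_mask, ref)

    def test_nonpositive_k_rejected(self, lesion_phantom):
        b = lesion_phantom
        ref = ReferenceStats(mean=100.0, sd=10.0, n_voxels=10)
        with pytest.raises(ValueError, match="k"):
            classify_edema(b.stir_t0, b.bone_mask, b.bone_mask, ref, k=0)

    def test_refined_map_is_subset(self, lesion_phantom):
        b = lesion_phantom
        ref = reference_stats(b.stir_t0, b.marrow_ref_mask)
        e = classify_edema(b.stir_t0, b.bone_mask, b.bone_mask, ref, min_cluster_voxels=10)
        r = refine_partial_volume(b.stir_t0, e, ref)
        assert np.all(np.asarray(r.mask.data) <= np.asarray(e.mask.data))


class TestChangeMaps:
    def _map(self, vol, arr, roi="Q1", tp="t0"):
        from periomri.edema import EdemaMap

        return EdemaMap(_mask_like(vol, arr), roi, tp, 120.0, 2.0)

    def test_equal_maps_all_stable(self):
        vol = ImageVolume(np.zeros((10, 10, 10)))
        m = np.zeros((10, 10, 10)); m[3:6, 3:6, 3:6] = 1
        rep, red, new = change_maps(self._map(vol, m), self._map(vol, m, tp="t1"))
        assert rep.reduction_mm3 == 0
        assert rep.new_mm3 == 0
        assert rep.stable_mm3 == pytest.approx(27 * 0.65**3)

    def test_forced_arithmetic_1000_voxels(self):
        vol = ImageVolume(np.zeros((20, 20, 20)))
        m = np.zeros((20, 20, 20)); m.ravel()[:1000] = 1
        rep, red, new = change_maps(
            self._map(vol, m), self._map(vol, np.zeros_like(m), tp="t1")
        )
        assert rep.reduction_mm3 == pytest.approx(1000 * 0.65**3)  # 274.625
        assert rep.new_mm3 == 0

    def test_volume_conservation_identity(self):
        rng = np.random.default_rng(10)
        vol = ImageVolume(np.zeros((16, 16, 16)))
        for _ in range(10):
            a = rng.random((16, 16, 16)) < 0.3
            b = rng.random((16, 16, 16)) < 0.3
            e0, e1 = self._map(vol, a), self._map(vol, b, tp="t1")
            rep, red, new = change_maps(e0, e1)
            assert rep.reduction_mm3 + rep.stable_mm3 == pytest.approx(e0.volume_mm3)
            assert rep.new_mm3 + rep.stable_mm3 == pytest.approx(e1.volume_mm3)

    def test_grid_mismatch_rejected(self):
        v1 = ImageVolume(np.zeros((8, 8, 8)))
        v2 = ImageVolume(np.zeros((9, 9, 9)))
        with pytest.raises(ValueError, match="grid"):
            change_maps(self._map(v1, np.zeros((8,) * 3)), self._map(v2, np.zeros((9,) * 3)))


class TestEdemaDepth:
    def _site(self, crest, direction=(0, 0, -1.0)):
        return ToothSite(36, "buccal-mid", np.array(crest, float), np.array(direction))

    def _map(self, vol, arr):
        from periomri.edema import EdemaMap

        return EdemaMap(_mask_like(vol, arr), "all", "t0", 120.0, 2.0)

    def test_no_edema_gives_zero(self):
        vol = ImageVolume(np.zeros((16, 16, 16)))
        e = self._map(vol, np.zeros((16, 16, 16)))
        assert edema_depth(e, self._site([5, 5, 9])) == 0.0

    def test_contiguous_run_of_four_voxels(self):
        """Edema spanning 4 voxel centers along the ray reads ~2.6 mm
        (within one voxel of 4 x 0.65)."""
        vol = ImageVolume(np.zeros((16, 16, 16)))
        m = np.zeros((16, 16, 16)); m[8, 8, 6:10] = 1
        e = self._map(vol, m)
        site = self._site([8 * 0.65, 8 * 0.65, 14 * 0.65])
        ed = edema_depth(e, site)
        assert abs(ed - 2.6) <= 0.65

    def test_phantom_lesion_extent_recovered(self):
        """Lesion reaching 5 mm along the site axis: ED within one voxel."""
        cfg = PhantomConfig(
            lesions_t0=[LesionSpec((20, 20, 20), (3, 3, 2.5), 6.0)], noise_sd=0.0
        )
        b = generate_phantom(cfg)
        ref = ReferenceStats(mean=100.0, sd=10.0, n_voxels=1000)
        e = classify_edema(b.stir_t0, b.bone_mask, b.bone_mask, ref)
        site = self._site([20.0, 20.0, 27.0])
        assert abs(edema_depth(e, site) - 5.0) <= 0.65

    def test_rounding_to_integer_mm(self):
        vol = ImageVolume(np.zeros((16, 16, 16)))
        m = np.zeros((16, 16, 16)); m[8, 8, 6:10] = 1
        e = self._map(vol, m)
        site = self._site([8 * 0.65, 8 * 0.65, 14 * 0.65])
        assert edema_depth(e, site, rounding="nearest_mm") == float(
            np.floor(edema_depth(e, site) + 0.5)
        )

    def test_ray_leaving_grid_warns_and_zero(self):
        vol = ImageVolume(np.zeros((16, 16, 16)))
        e = self._map(vol, np.zeros((16, 16, 16)))
        # crest at the grid face, pointing straight out of the grid
        with pytest.warns(UserWarning, match="exits the grid"):
            ed = edema_depth(e, self._site([3.25, 3.25, 0.0], (0, 0, -1.0)))
        assert ed == 0.0

    def test_crest_outside_volume_rejected(self):
        vol = ImageVolume(np.zeros((16, 16, 16)))
        e = self._map(vol, np.zeros((16, 16, 16)))
        with pytest.raises(ValueError, match="outside"):
            edema_depth(e, self._site([5, 5, -2.0]))


class TestToothMaxDepth:
    def test_basic_and_symmetry(self):
        assert tooth_max_depth([0, 0, 0, 0, 0, 0]) == 0
        assert tooth_max_depth([1, 2, 3, 0, 0, 2]) == 3
        assert tooth_max_depth([3, 2, 1, 2, 0, 0]) == 3  # permutation invariant
        assert tooth_max_depth([4.5]) == 4.5  # missing sites allowed

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tooth_max_depth([])
        with pytest.raises(ValueError):
            tooth_max_depth([1] * 7)
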