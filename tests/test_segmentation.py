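"""Patch-based label fusion: weight arithmetic, brute-force oracle
equivalence, self-segmentation, ordering invariance, volumetry."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cardiatlas.core import Atlas, LandmarkSet, VolumeImage
from cardiatlas.phantom import PhantomSpec, generate_phantom
from cardiatlas.segmentation import (
    FusionParams,
    MultiAtlasSegmenter,
    _search_offsets,
    compute_volumetry,
    fuse_labels,
    fuse_on_common_grid,
    initialize_alignment,
    patch_similarity_weight,
)
from cardiatlas.transforms import SimilarityTransform


# ---------------------------------------------------------------------------
# Brute-force oracle: direct per-voxel loops over the documented contract.


def brute_force_fusion(target, spacing, atlas_pairs, params):
    """Independent re-implementation of weighted patch voting.

    For every voxel and every in-window offset whose displaced center stays
    in bounds, sample both patches with edge-clamped indices, weight by
    exp(-SSD/(h^2 n)) * exp(-||offset||^2/s^2), keep the n_best heaviest
    per atlas, vote by label, argmax with low-label ties.
    """
    tgt = np.asarray(target, dtype=float)
    sp = np.asarray(spacing, dtype=float)
    h = params.similarity_bandwidth
    assert h is not None, "oracle requires an explicit bandwidth" 
    s = params.spatial_bandwidth or params.search_radius_mm or 1.0
    ext = params.patch_extent_voxels(sp)
    half = [e // 2 for e in ext]
    offs = _search_offsets(sp, params.search_radius_mm)
    shape = tgt.shape

    def clamp(i, ax):
        return min(max(i, 0), shape[ax] - 1)

    def patch(arr, center, shift=(0, 0, 0)):
        vals = []
        for du in range(-half[0], half[0] + 1):
            for dv in range(-half[1], half[1] + 1):
                for dw in range(-half[2], half[2] + 1):
                    i = clamp(center[0] + du, 0)
                    j = clamp(center[1] + dv, 1)
                    k = clamp(center[2] + dw, 2)
                    vals.append(
                        arr[clamp(i + shift[0], 0), clamp(j + shift[1], 1), clamp(k + shift[2], 2)]
                    )
        return np.array(vals)

    out = np.zeros(shape, dtype=np.int16)
    for v in np.ndindex(shape):
        tp = patch(tgt, v)
        scores = np.zeros(4)
        for gray, labels in atlas_pairs:
            cand = []
            for off in offs:
                w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if not all(0 <= w[a] < shape[a] for a in range(3)):
                    continue
                ap = patch(np.asarray(gray, dtype=float), v, tuple(off))
                ssd = float(((tp - ap) ** 2).sum())
                wgt = np.exp(-ssd / (h**2 * tp.size)) * np.exp(
                    -float(((off * sp) ** 2).sum()) / s**2
                )
                cand.append((wgt, int(labels[w])))
            cand.sort(key=lambda t: -t[0])
            for wgt, lab in cand[: params.n_best_patches]:
                scores[lab] += wgt
        out[v] = int(np.argmax(scores))
    return out


class TestFusionOracle:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_on_tiny_volumes(self, seed):
        """Vectorised fusion equals exhaustive per-voxel voting exactly."""
        rng = np.random.default_rng(seed)
        shape = (7, 6, 5)
        spacing = (2.0, 2.0, 2.0)
        from scipy.ndimage import gaussian_filter

        target = gaussian_filter(rng.normal(size=shape), 1.0)
        pairs = []
        for _ in range(2):
            gray = target + 0.2 * gaussian_filter(rng.normal(size=shape), 1.0)
            labels = (gaussian_filter(rng.normal(size=shape), 1.5) > 0).astype(
                np.int16
            ) + (gaussian_filter(rng.normal(size=shape), 1.5) > 0.5).astype(np.int16)
            pairs.append((gray, labels))
        params = FusionParams(
            patch_size_mm=5.0, search_radius_mm=4.0, n_best_patches=3,
            similarity_bandwidth=0.7, spatial_bandwidth=4.0,
        )
        fused, _ = fuse_on_common_grid(target, spacing, pairs, params)
        oracle = brute_force_fusion(target, spacing, pairs, params)
        assert np.array_equal(fused, oracle)


class TestPatchWeight:
    def test_identical_patches_zero_offset_weight_one(self):
        params = FusionParams(similarity_bandwidth=2.0)
        p = np.arange(27.0).reshape(3, 3, 3)
        assert patch_similarity_weight(p, p, (0, 0, 0), params) == pytest.approx(1.0)

    def test_hand_computed_two_voxel_patch(self):
        """SSD=8 with h^2 n = 8 and zero offset gives exactly e^-1."""
        params = FusionParams(similarity_bandwidth=2.0, spatial_bandwidth=3.0)
        t = np.array([[[0.0, 0.0]]])
        a = np.array([[[2.0, 2.0]]])
        w = patch_similarity_weight(t, a, (0, 0, 0), params)
        assert w == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_monotone_in_ssd_and_offset(self, rng):
        params = FusionParams(similarity_bandwidth=1.0, spatial_bandwidth=5.0)
        t = rng.normal(size=(3, 3, 3))
        w0 = patch_similarity_weight(t, t + 0.1, (0, 0, 0), params)
        w1 = patch_similarity_weight(t, t + 0.5, (0, 0, 0), params)
        w2 = patch_similarity_weight(t, t + 0.5, (3, 0, 0), params)
        assert w0 > w1 > w2


class TestInitializeAlignment:
    def _landmarks(self, rng):
        from cardiatlas.core import LANDMARK_NAMES

        return LandmarkSet({n: rng.normal(size=3) * 15 for n in LANDMARK_NAMES})

    def test_identity_for_equal_sets(self, rng):
        lms = self._landmarks(rng)
        tf, res = initialize_alignment(lms, lms)
        np.testing.assert_allclose(tf.matrix, np.eye(4), atol=1e-10)
        assert res == pytest.approx(0.0, abs=1e-10)

    def test_recovers_rotation_and_translation(self, rng):
        atlas_lms = self._landmarks(rng)
        true = SimilarityTransform(
            Rotation.from_euler("y", 10, degrees=True).as_matrix(),
            np.array([3.0, 1.0, -2.0]),
        )
        target_lms = atlas_lms.transformed(true)
        tf, res = initialize_alignment(target_lms, atlas_lms)
        np.testing.assert_allclose(tf.matrix, true.matrix, atol=1e-6)
        assert res < 1e-9


class TestFuseLabels:
    def test_self_segmentation_is_exact_noiseless(self):
        spec = PhantomSpec(noise_sd=0.0, rng_seed=5)
        gray, labels, lms, _ = generate_phantom(spec, (3.0, 3.0, 3.0))
        atlas = Atlas(gray, labels, lms, "self")
        fused = fuse_labels(gray, [atlas], FusionParams(search_radius_mm=6.0), lms)
        assert np.array_equal(fused.data, labels.data)

    def test_invariant_to_atlas_ordering(self, atlas_pool_small):
        target = atlas_pool_small[0]
        pool = atlas_pool_small[1:4]
        params = FusionParams(search_radius_mm=6.0)
        f1 = fuse_labels(target.intensity, pool, params, target.landmarks)
        f2 = fuse_labels(target.intensity, pool[::-1], params, target.landmarks)
        assert np.array_equal(f1.data, f2.data)

    def test_empty_pool_rejected(self, lv_phantom):
        gray = lv_phantom[0]
        with pytest.raises(ValueError, match="at least one"):
            fuse_labels(gray, [])


class TestEstimatorInterface:
    def test_fit_predict_and_get_params(self, atlas_pool_small):
        seg = MultiAtlasSegmenter(search_radius_mm=6.0, n_best_patches=3)
        assert seg.get_params()["n_best_patches"] == 3
        seg.set_params(n_best_patches=5)
        seg.fit(atlas_pool_small[1:3])
        assert seg.n_atlases_ == 2
        target = atlas_pool_small[0]
        labels = seg.predict(target.intensity, target.landmarks)
        assert labels.same_grid(target.intensity)
        from cardiatlas.metrics import dice_coefficient

        assert dice_coefficient(labels, target.labels, 2) > 0.9

    def test_predict_before_fit_raises(self, lv_phantom):
        with pytest.raises(RuntimeError, match="not fitted"):
            MultiAtlasSegmenter().predict(lv_phantom[0])


class TestVolumetry:
    def test_counting_arithmetic(self):
        data = np.zeros((20, 20, 20), dtype=np.int16)
        data[:10, :10, :5] = 2  # 500 voxels myocardium
        data[:10, :10, 5:7] = 1  # 200 voxels cavity
        labels = VolumeImage(data, (1.0, 1.0, 1.0))
        v = compute_volumetry(labels, body_surface_area_m2=2.0)
        assert v.lv_mass_g == pytest.approx(0.5 * 1.05)
        assert v.lvedv_ml == pytest.approx(0.2)
        assert v.lvedvi_ml_per_m2 == pytest.approx(0.1)
        assert v.lvmi_g_per_m2 == pytest.approx(0.2625)

    def test_mass_constant_1000_unit_voxels(self):
        data = np.zeros((10, 10, 10), dtype=np.int16)
        data.ravel()[:1000] = 2
        labels = VolumeImage(data, (1.0, 1.0, 1.0))
        assert compute_volumetry(labels, 1.0).lv_mass_g == pytest.approx(1.05)

    def test_sphere_phantom_close_to_analytic(self, sphere_phantom):
        _, labels, _, gt, _ = sphere_phantom
        v = compute_volumetry(labels, 1.0)
        assert v.lvedv_ml == pytest.approx(gt.cavity_volume() / 1000, rel=0.02)
        assert v.lv_mass_g == pytest.approx(
            1.05 * gt.myocardium_volume() / 1000, rel=0.02
        )

    def test_empty_myocardium_rejected(self):
        labels = VolumeImage(np.zeros((5, 5, 5), dtype=np.int16), (1, 1, 1))
        with pytest.raises(ValueError, match="myocardium"):
            compute_volumetry(labels, 1.0)
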