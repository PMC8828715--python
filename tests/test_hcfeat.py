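"""Handcrafted feature catalogue: values, oracles, invariances."""

import numpy as np
import pytest
import pywt
from scipy.ndimage import correlate1d

from _oracles import brute_force_glcm
from radiofuse.core import VolumeWithMask
from radiofuse.hcfeat import (
    DEFAULT_OFFSETS,
    GLCM_NAMES,
    HCConfig,
    extract_hc,
    first_order,
    glcm_features,
    glcm_matrix,
    glcm_stats,
    hc_feature_names,
    quantise,
    shape_features,
    wavelet_bands,
    wavelet_features,
)


def _vm(intens, mask=None, spacing=(1.0, 1.0, 1.0)):
    intens = np.asarray(intens, dtype=float)
    if mask is None:
        mask = np.ones(intens.shape, dtype=bool)
    return VolumeWithMask(intens, mask, spacing)


def _roi_vm(values):
    """Embed a 1D multiset of ROI values in a line volume."""
    arr = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    return _vm(arr)


class TestFirstOrder:
    def test_three_point_statistics(self):
        fv = dict(zip(first_order(_roi_vm([10, 20, 30])).names,
                      first_order(_roi_vm([10, 20, 30])).values))
        assert fv["firstorder.mean"] == 20
        assert fv["firstorder.range"] == 20
        assert fv["firstorder.median"] == 20

    def test_constant_roi_degenerate_statistics(self):
        fv = dict(zip(first_order(_roi_vm([7.0] * 10)).names,
                      first_order(_roi_vm([7.0] * 10)).values))
        assert fv["firstorder.variance"] == 0
        assert fv["firstorder.entropy"] == 0
        assert fv["firstorder.uniformity"] == 1

    def test_median_absolute_deviation_hand_value(self):
        fv = dict(zip(first_order(_roi_vm([1, 2, 3, 4, 5])).names,
                      first_order(_roi_vm([1, 2, 3, 4, 5])).values))
        # |x - 3| = {2, 1, 0, 1, 2}; median = 1
        assert fv["firstorder.mad"] == 1

    def test_feature_count(self):
        assert len(first_order(_roi_vm([1, 2, 3]))) == 19


class TestShape:
    def test_single_voxel_unit_cube(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        fv = dict(zip(shape_features(_vm(np.ones((3, 3, 3)), mask)).names,
                      shape_features(_vm(np.ones((3, 3, 3)), mask)).values))
        assert fv["shape.volume_mm3"] == 1.0
        assert fv["shape.surface_area_mm2"] == 6.0

    def test_domino_block_exposed_faces(self):
        mask = np.zeros((4, 3, 3), dtype=bool)
        mask[1:3, 1, 1] = True
        fv = dict(zip(shape_features(_vm(np.ones((4, 3, 3)), mask)).names,
                      shape_features(_vm(np.ones((4, 3, 3)), mask)).values))
        assert fv["shape.volume_mm3"] == 2.0
        assert fv["shape.surface_area_mm2"] == 10.0

    def test_digital_ball_is_nearly_spherical(self, ball_phantom):
        fv = dict(zip(shape_features(ball_phantom).names,
                      shape_features(ball_phantom).values))
        assert abs(fv["shape.sphericity"] - 1.0) < 0.15
        assert fv["shape.max_diameter_mm"] == pytest.approx(20.0, rel=0.05)

    def test_shape_ignores_intensity_scaling(self, textured_phantom):
        doubled = VolumeWithMask(textured_phantom.intensities * 2,
                                 textured_phantom.mask,
                                 textured_phantom.spacing)
        a = shape_features(textured_phantom)
        b = shape_features(doubled)
        np.testing.assert_array_equal(a.values, b.values)
        assert len(a) == 17

    def test_volume_respects_spacing(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        fv = dict(zip(
            shape_features(_vm(np.ones((3, 3, 3)), mask, (2, 3, 4))).names,
            shape_features(_vm(np.ones((3, 3, 3)), mask, (2, 3, 4))).values))
        assert fv["shape.volume_mm3"] == 24.0
        assert fv["shape.surface_area_mm2"] == 2 * (6 + 8 + 12)


class TestGLCM:
    def test_two_level_plane_hand_example(self):
        arr = np.array([[0.0, 0.0], [1.0, 1.0]]).reshape(2, 2, 1)
        vm = _vm(arr)
        fv = dict(zip(glcm_features(vm, n_bins=2, offsets=((0, 1, 0),)).names,
                      glcm_features(vm, n_bins=2, offsets=((0, 1, 0),)).values))
        assert fv["glcm.contrast"] == 0.0
        assert fv["glcm.maximum_probability"] == 0.5

    def test_constant_roi_degenerate_matrix(self):
        fv = dict(zip(glcm_features(_vm(np.full((3, 3, 3), 5.0))).names,
                      glcm_features(_vm(np.full((3, 3, 3), 5.0))).values))
        assert fv["glcm.joint_energy"] == 1.0
        assert fv["glcm.joint_entropy"] == 0.0

    def test_matrix_is_symmetric_and_normalised(self, textured_phantom):
        levels = np.zeros(textured_phantom.mask.shape, dtype=np.intp)
        levels[textured_phantom.mask] = quantise(
            textured_phantom.roi_values, 16)
        P = glcm_matrix(levels, textured_phantom.mask, 16, DEFAULT_OFFSETS)
        assert P.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(P, P.T)

    def test_single_voxel_roi_rejected(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        with pytest.raises(ValueError, match="2 voxels"):
            glcm_features(_vm(np.ones((3, 3, 3)), mask))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(3, 7, size=3))
        intens = rng.uniform(0, 100, size=shape)
        mask = rng.random(shape) < 0.7
        mask.flat[0] = True
        mask.flat[-1] = True
        vm = _vm(intens, mask)
        n_bins = 6
        levels = np.zeros(shape, dtype=np.intp)
        levels[mask] = quantise(intens[mask], n_bins)
        P_ref = brute_force_glcm(levels, mask, n_bins, DEFAULT_OFFSETS)
        P = glcm_matrix(levels, mask, n_bins, DEFAULT_OFFSETS)
        np.testing.assert_allclose(P, P_ref, atol=1e-10)
        # spot-check statistics against direct formulas on the oracle matrix
        stats = glcm_stats(P)
        i = np.arange(1, n_bins + 1)
        ii, jj = np.meshgrid(i, i, indexing="ij")
        assert stats["contrast"] == pytest.approx(
            ((ii - jj) ** 2 * P_ref).sum(), abs=1e-10)
        assert stats["dissimilarity"] == pytest.approx(
            (np.abs(ii - jj) * P_ref).sum(), abs=1e-10)
        assert stats["joint_energy"] == pytest.approx(
            (P_ref ** 2).sum(), abs=1e-10)
        assert stats["maximum_probability"] == pytest.approx(
            P_ref.max(), abs=1e-10)
        nz = P_ref > 0
        assert stats["joint_entropy"] == pytest.approx(
            -(P_ref[nz] * np.log2(P_ref[nz])).sum(), abs=1e-10)


class TestWavelet:
    def test_detail_bands_of_constant_volume_vanish(self):
        vm = _vm(np.full((12, 12, 12), 3.0))
        fv = dict(zip(wavelet_features(vm).names, wavelet_features(vm).values))
        for band in ("LLH", "LHL", "HLH", "HHH"):
            assert fv[f"wavelet.{band}.firstorder.mean"] == pytest.approx(
                0.0, abs=1e-10)

    def test_band_count_times_feature_count(self, textured_phantom):
        assert len(wavelet_features(textured_phantom)) == 368

    def test_lowpass_band_matches_separable_convolution_oracle(self):
        rng = np.random.default_rng(0)
        vol = np.cumsum(rng.normal(size=(16, 16, 16)), axis=0)
        bands = wavelet_bands(vol, "coif1")
        lo = np.array(pywt.Wavelet("coif1").dec_lo)
        ref = vol.copy()
        for ax in range(3):
            ref = correlate1d(ref, lo[::-1], axis=ax, mode="wrap")
        ref = np.roll(ref, (-1, -1, -1), axis=(0, 1, 2))
        centre = (slice(3, 13),) * 3
        assert np.mean(bands["LLL"][centre]) == pytest.approx(
            np.mean(ref[centre]), rel=0.05)

    def test_too_small_volume_rejected(self):
        with pytest.raises(ValueError, match="filter length"):
            wavelet_bands(np.ones((4, 12, 12)), "coif1")


class TestCatalogue:
    def test_default_catalogue_has_431_unique_named_features(
            self, textured_phantom):
        fv = extract_hc(textured_phantom)
        assert len(fv) == 431
        assert len(set(fv.names)) == 431
        assert fv.names == hc_feature_names()
        assert np.all(np.isfinite(fv.values))

    def test_extraction_is_deterministic(self, textured_phantom):
        a = extract_hc(textured_phantom)
        b = extract_hc(textured_phantom)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.names == b.names

    def test_rotation_invariance_of_rotation_invariant_features(
            self, textured_phantom):
        rot = VolumeWithMask(
            np.rot90(textured_phantom.intensities, axes=(0, 1)),
            np.rot90(textured_phantom.mask, axes=(0, 1)),
            (textured_phantom.spacing[1], textured_phantom.spacing[0],
             textured_phantom.spacing[2]))
        a = extract_hc(textured_phantom)
        b = extract_hc(rot)
        av = dict(zip(a.names, a.values))
        bv = dict(zip(b.names, b.values))
        for name in [n for n in a.names if n.startswith("firstorder.")] + [
                "shape.volume_mm3", "shape.sphericity",
                "shape.max_diameter_mm", "shape.elongation"]:
            assert av[name] == pytest.approx(bv[name], abs=1e-9), name

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_all_features_finite_on_random_phantoms(self, seed):
        from radiofuse.synthcohort import PhantomSpec, generate_phantom

        rng = np.random.default_rng(seed)
        spec = PhantomSpec(
            grid_shape=(26, 26, 26),
            semi_axes=tuple(rng.uniform(4, 10, 3)),
            texture_scale=float(rng.uniform(10, 120)),
        )
        fv = extract_hc(generate_phantom(spec, seed))
        assert np.all(np.isfinite(fv.values))
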