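"""Ratio-field estimation, filtering, and the full correction pipeline."""

import numpy as np
import pytest
from scipy import signal

from cbctprior.correction import (
    FilterSpec,
    MaskedRatio,
    compute_ratio_field,
    correct_cbct,
    enhance_part,
    hu_to_mu,
    mu_to_hu,
    smooth_ratio_field,
)
from cbctprior.phantom import DegradationSpec, PhantomSpec, degrade_to_cbct, generate_phantom_ct
from cbctprior.volume_io import ImageGrid, IntensityUnit, VolumetricImage

from conftest import make_image


class TestMuScale:
    @pytest.mark.parametrize("hu,mu", [(-1000.0, 0.0), (0.0, 1.0), (500.0, 1.5)])
    def test_hu_to_mu_values(self, hu, mu):
        img = make_image(shape=(4, 4, 4), value=hu)
        assert hu_to_mu(img).voxels[0, 0, 0] == pytest.approx(mu)

    def test_round_trip_above_floor(self):
        img = make_image(shape=(4, 4, 4), value=-123.0)
        back = mu_to_hu(hu_to_mu(img))
        np.testing.assert_allclose(back.voxels, img.voxels, atol=1e-12)

    def test_below_floor_clamped_to_zero(self):
        img = make_image(shape=(4, 4, 4), value=-1500.0)
        assert np.all(hu_to_mu(img).voxels == 0.0)


def _mu_image(value, shape=(8, 8, 8)):
    return make_image(shape=shape, value=value, unit=IntensityUnit.MU_RELATIVE)


class TestComputeRatio:
    def test_equal_images_give_unity(self):
        mask = np.ones((8, 8, 8), bool)
        r = compute_ratio_field(_mu_image(1.0), _mu_image(1.0), mask)
        assert np.all(r.values[r.defined] == 1.0)
        assert r.defined.all()

    def test_simple_quotient(self):
        mask = np.ones((8, 8, 8), bool)
        r = compute_ratio_field(_mu_image(1.0), _mu_image(0.8), mask)
        np.testing.assert_allclose(r.values[r.defined], 1.25)

    def test_zero_denominator_clamps_to_ceiling(self):
        mask = np.ones((8, 8, 8), bool)
        r = compute_ratio_field(_mu_image(1.0), _mu_image(0.0), mask)
        assert np.all(r.values[r.defined] == 5.0)

    def test_air_over_air_is_undefined(self):
        mask = np.ones((8, 8, 8), bool)
        r = compute_ratio_field(_mu_image(0.0), _mu_image(0.0), mask)
        assert not r.defined.any()

    def test_empty_mask_warns(self):
        mask = np.zeros((8, 8, 8), bool)
        with pytest.warns(UserWarning, match="empty class mask"):
            r = compute_ratio_field(_mu_image(1.0), _mu_image(1.0), mask)
        assert not r.defined.any()


class TestSmoothRatio:
    grid = ImageGrid(shape=(40, 40, 20), spacing=(2.5, 2.5, 2.5))

    def _mask(self):
        m = np.zeros(self.grid.shape, bool)
        m[5:35, 5:35, 3:17] = True
        return m

    def test_constant_field_preserved(self):
        mask = self._mask()
        mr = MaskedRatio(values=np.where(mask, 1.25, 1.0), defined=mask.copy())
        out = smooth_ratio_field(mr, mask, self.grid)
        np.testing.assert_allclose(out[mask], 1.25, atol=1e-12)
        assert np.all(out[~mask] == 1.0)

    def test_huge_width_converges_to_defined_mean(self):
        mask = self._mask()
        rng = np.random.default_rng(1)
        vals = np.where(mask, rng.uniform(0.8, 1.3, self.grid.shape), 1.0)
        mr = MaskedRatio(values=vals, defined=mask.copy())
        out = smooth_ratio_field(mr, mask, self.grid, FilterSpec(width_mm=10000.0))
        assert np.abs(out[mask] - vals[mask].mean()).max() < 1e-3

    def test_checkerboard_flattens_to_unity(self):
        # high-frequency 0.9/1.1 alternation at 1-voxel period is far above
        # the 20 mm cutoff and must smooth to ~1 in the mask interior
        mask = self._mask()
        ii, jj, kk = np.indices(self.grid.shape)
        cb = np.where((ii + jj + kk) % 2 == 0, 0.9, 1.1)
        mr = MaskedRatio(values=np.where(mask, cb, 1.0), defined=mask.copy())
        out = smooth_ratio_field(mr, mask, self.grid, FilterSpec(width_mm=20.0))
        from scipy import ndimage
        interior = ndimage.binary_erosion(mask, iterations=4)
        assert np.abs(out[interior] - 1.0).max() < 1e-2

    def test_matches_explicit_convolution_oracle(self):
        # independent oracle: build the separable Gaussian kernel from its
        # formula and convolve numerator/denominator with FFT convolution
        mask = self._mask()
        rng = np.random.default_rng(4)
        vals = np.where(mask, rng.uniform(0.7, 1.4, self.grid.shape), 1.0)
        mr = MaskedRatio(values=vals, defined=mask.copy())
        spec = FilterSpec(width_mm=20.0)
        out = smooth_ratio_field(mr, mask, self.grid, spec)

        sigma_vox = spec.width_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / 2.5
        radius = int(4.0 * sigma_vox + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-x ** 2 / (2 * sigma_vox ** 2))
        k1 /= k1.sum()
        kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        w = mask.astype(float)
        num = signal.fftconvolve(vals * w, kernel, mode="same")
        den = signal.fftconvolve(w, kernel, mode="same")
        expected = np.where(den > 1e-6, num / np.maximum(den, 1e-12), vals[mask].mean())
        np.testing.assert_allclose(out[mask], np.clip(expected, 0.2, 5.0)[mask],
                                   atol=5e-4)

    def test_all_undefined_rejected(self):
        mr = MaskedRatio(values=np.ones(self.grid.shape),
                         defined=np.zeros(self.grid.shape, bool))
        with pytest.raises(ValueError):
            smooth_ratio_field(mr, self._mask(), self.grid)

    def test_median_kind_preserves_constants(self):
        mask = self._mask()
        mr = MaskedRatio(values=np.where(mask, 1.1, 1.0), defined=mask.copy())
        out = smooth_ratio_field(mr, mask, self.grid, FilterSpec(kind="median"))
        np.testing.assert_allclose(out[mask], 1.1, atol=1e-12)


class TestEnhancePart:
    def test_unity_ratio_is_identity(self):
        cb = _mu_image(0.8)
        mask = np.ones(cb.grid.shape, bool)
        out = enhance_part(cb, np.ones(cb.grid.shape), mask)
        np.testing.assert_allclose(out, 0.8)

    def test_ratio_times_value(self):
        cb = _mu_image(0.8)
        mask = np.ones(cb.grid.shape, bool)
        out = enhance_part(cb, np.full(cb.grid.shape, 1.25), mask)
        np.testing.assert_allclose(out, 1.0)

    def test_empty_mask_gives_zeros(self):
        cb = _mu_image(0.8)
        out = enhance_part(cb, np.ones(cb.grid.shape), np.zeros(cb.grid.shape, bool))
        assert np.all(out == 0.0)


class TestCorrectCbct:
    def test_identity_input_returns_itself(self, phantom0):
        ct, _ = phantom0
        res = correct_cbct(ct, ct, None)
        assert np.abs(res.corrected.voxels - ct.voxels).max() <= 1.0

    def test_fov_completion_is_exact(self, fixture0, corrected_aligned):
        res = corrected_aligned
        outside = ~res.fov
        assert outside.any()
        np.testing.assert_array_equal(res.corrected.voxels[outside],
                                      fixture0.ct.voxels[outside])

    def test_smooth_multiplicative_bias_removed(self, phantom0):
        # pure cupping (no noise, no shifts): correction must remove most
        # of the artifact energy
        ct, masks = phantom0
        spec = DegradationSpec(cupping_amplitude=0.15, cupping_length_mm=80.0,
                               arc_shading_amplitude=0.0,
                               per_class_hu_shift=(0, 0, 0, 0),
                               noise_sd_hu=0.0, fov_radius_mm=1e6)
        deg = degrade_to_cbct(ct, masks, spec)
        res = correct_cbct(ct, deg.cbct, None, fov_mask=deg.fov)
        body = masks.body & res.fov
        mae_orig = np.abs(deg.cbct.voxels - ct.voxels)[body].mean()
        mae_corr = np.abs(res.corrected.voxels - ct.voxels)[body].mean()
        assert mae_corr <= 0.3 * mae_orig

    def test_global_scale_absorbed_by_ratio(self, fixture0, corrected_aligned):
        fx = fixture0
        mu = hu_to_mu(fx.cbct_aligned)
        scaled_hu = mu_to_hu(mu.copy_with(mu.voxels * 1.2))
        scaled = scaled_hu.copy_with(
            np.where(fx.fov_aligned, scaled_hu.voxels, -1000.0))
        res = correct_cbct(fx.ct, scaled, None, fov_mask=fx.fov_aligned)
        delta = np.abs(res.corrected.voxels
                       - corrected_aligned.corrected.voxels)[fx.truth_masks.body]
        assert delta.mean() <= 2.0
        assert np.percentile(delta, 99) <= 2.0

    def test_noise_only_degradation_not_amplified(self, phantom0):
        ct, masks = phantom0
        spec = DegradationSpec(cupping_amplitude=0.0, arc_shading_amplitude=0.0,
                               per_class_hu_shift=(0, 0, 0, 0),
                               noise_sd_hu=15.0, seed=2)
        deg = degrade_to_cbct(ct, masks, spec)
        res = correct_cbct(ct, deg.cbct, None, fov_mask=deg.fov)
        body = masks.body & res.fov
        sd_orig = (deg.cbct.voxels - ct.voxels)[body].std()
        sd_corr = (res.corrected.voxels - ct.voxels)[body].std()
        assert sd_corr <= 1.05 * sd_orig

    def test_wide_filter_restores_class_means(self, fixture0):
        fx = fixture0
        res = correct_cbct(fx.ct, fx.cbct_aligned, None,
                           spec=FilterSpec(width_mm=5000.0),
                           fov_mask=fx.fov_aligned)
        diff = res.corrected.voxels - fx.ct.voxels
        region = fx.truth_masks.body & res.fov
        for name in ("lung", "soft", "bone"):
            cmask = fx.truth_masks.class_mask(name) & region
            assert abs(diff[cmask].mean()) < 5.0, name

    def test_ratio_fields_respect_bounds(self, corrected_aligned):
        for name, img in corrected_aligned.ratio_fields.items():
            assert img.voxels.min() >= 0.2 and img.voxels.max() <= 5.0, name

    def test_non_overlapping_supports_rejected(self, phantom0):
        from cbctprior.correction import CorrectionError
        from cbctprior.volume_io import RigidTransform
        ct, _ = phantom0
        far = RigidTransform(translation_mm=(10000.0, 0.0, 0.0))
        with pytest.raises(CorrectionError):
            correct_cbct(ct, ct, far)
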