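"""Histograms, HU-error metrics, density calibration, and WEPL rays."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbctprior.evaluation import (
    ConfigurationError,
    DensityCalibration,
    default_hu_edges,
    histogram_distance,
    hu_error_metrics,
    hu_to_density,
    intensity_histogram,
    wepl_along_ray,
    wepl_discrepancy_map,
)
from cbctprior.segmentation import TissueMaskSet
from cbctprior.volume_io import ImageGrid, IntensityUnit, VolumetricImage

from conftest import make_image


class TestIntensityHistogram:
    def test_constant_image_fills_single_bin(self):
        img = make_image(shape=(5, 5, 4), value=0.0)
        h = intensity_histogram(img, np.ones(img.grid.shape, bool))
        assert h.counts.sum() == 100
        assert h.counts.max() == 100
        edges = h.bin_edges
        idx = int(np.argmax(h.counts))
        assert edges[idx] <= 0.0 < edges[idx + 1]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_counts_conserve_masked_voxels(self, seed):
        rng = np.random.default_rng(seed)
        img = make_image(shape=(8, 8, 8))
        img.voxels[:] = rng.normal(0, 2000, img.grid.shape)  # exceeds the range
        mask = rng.random(img.grid.shape) < 0.5
        if not mask.any():
            mask[0, 0, 0] = True
        h = intensity_histogram(img, mask)
        assert h.counts.sum() == mask.sum()

    def test_phantom_histogram_modes_at_class_means(self, phantom0):
        ct, masks = phantom0
        h = intensity_histogram(ct, np.ones(ct.grid.shape, bool))
        centers = (h.bin_edges[:-1] + h.bin_edges[1:]) / 2.0
        for mean in (-1000.0, -750.0, 40.0, 700.0):
            near = np.abs(centers - mean) <= 50.0
            peak = centers[near][np.argmax(h.counts[near])]
            assert abs(peak - mean) <= 10.0

    def test_empty_mask_rejected(self):
        img = make_image()
        with pytest.raises(ValueError):
            intensity_histogram(img, np.zeros(img.grid.shape, bool))


class TestHistogramDistance:
    def _hist(self, counts):
        edges = np.arange(len(counts) + 1, dtype=float) * 10.0
        from cbctprior.evaluation import IntensityHistogram
        return IntensityHistogram(bin_edges=edges, counts=np.asarray(counts))

    @pytest.mark.parametrize("metric", ["l1", "chi2", "emd"])
    def test_identical_histograms_are_zero(self, metric):
        h = self._hist([3, 5, 2, 0, 7])
        assert histogram_distance(h, h, metric) == 0.0

    def test_emd_closed_form_for_disjoint_bins(self):
        a = self._hist([10, 0, 0, 0, 0])
        b = self._hist([0, 0, 0, 10, 0])
        assert histogram_distance(a, b, "emd") == pytest.approx(3 * 10.0)

    def test_l1_matches_brute_force(self):
        rng = np.random.default_rng(5)
        a = self._hist(rng.integers(0, 50, 20))
        b = self._hist(rng.integers(0, 50, 20))
        expected = float(np.sum(np.abs(a.frequencies - b.frequencies)))
        assert histogram_distance(a, b, "l1") == pytest.approx(expected)

    def test_l1_and_emd_are_symmetric(self):
        rng = np.random.default_rng(6)
        a = self._hist(rng.integers(0, 50, 12))
        b = self._hist(rng.integers(0, 50, 12))
        for metric in ("l1", "emd"):
            assert histogram_distance(a, b, metric) == pytest.approx(
                histogram_distance(b, a, metric))

    def test_mismatched_edges_rejected(self):
        from cbctprior.evaluation import IntensityHistogram
        a = self._hist([1, 2, 3])
        b = IntensityHistogram(bin_edges=np.array([0.0, 5.0, 10.0, 15.0]),
                               counts=np.array([1, 2, 3]))
        with pytest.raises(ValueError):
            histogram_distance(a, b)


def _full_masks(grid):
    body = np.ones(grid.shape, bool)
    return TissueMaskSet(grid=grid, air=np.zeros(grid.shape, bool),
                         lung=np.zeros(grid.shape, bool), soft=body,
                         bone=np.zeros(grid.shape, bool), body=body)


class TestHuErrorMetrics:
    def test_equal_images_give_zero(self):
        img = make_image(value=40.0)
        rep = hu_error_metrics(img, img, _full_masks(img.grid))
        assert rep.mae_hu == 0.0 and rep.rmse_hu == 0.0

    def test_constant_offset(self):
        ref = make_image(value=40.0)
        test = make_image(value=50.0)
        rep = hu_error_metrics(test, ref, _full_masks(ref.grid))
        assert rep.mae_hu == pytest.approx(10.0)
        assert rep.rmse_hu == pytest.approx(10.0)
        assert rep.class_mean_error_hu["soft"] == pytest.approx(10.0)

    def test_matches_naive_voxel_loops(self):
        rng = np.random.default_rng(8)
        ref = make_image(shape=(6, 6, 6), value=0.0)
        test = make_image(shape=(6, 6, 6), value=0.0)
        ref.voxels[:] = rng.normal(0, 100, ref.grid.shape)
        test.voxels[:] = rng.normal(0, 100, ref.grid.shape)
        rep = hu_error_metrics(test, ref, _full_masks(ref.grid))
        abs_sum, sq_sum, n = 0.0, 0.0, 0
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    d = test.voxels[i, j, k] - ref.voxels[i, j, k]
                    abs_sum += abs(d)
                    sq_sum += d * d
                    n += 1
        assert rep.mae_hu == pytest.approx(abs_sum / n)
        assert rep.rmse_hu == pytest.approx(np.sqrt(sq_sum / n))


class TestDensityCalibration:
    @pytest.mark.parametrize("hu,rho", [(-1000.0, 0.001), (0.0, 1.0), (100.0, 1.05)])
    def test_control_points_and_interpolation(self, hu, rho):
        cal = DensityCalibration()
        assert cal.to_density(np.array(hu)) == pytest.approx(rho)

    def test_extrapolation_clamped(self):
        cal = DensityCalibration()
        assert cal.to_density(np.array(-2000.0)) == pytest.approx(0.001)
        assert cal.to_density(np.array(3000.0)) == pytest.approx(1.85)

    def test_non_monotone_curve_rejected(self):
        with pytest.raises(ConfigurationError):
            DensityCalibration(control_points=((-1000.0, 0.5), (0.0, 0.2)))


def _density_image(values, spacing=(1.0, 1.0, 1.0)):
    shape = values.shape
    grid = ImageGrid(shape=shape, spacing=spacing,
                     origin=tuple(-(n - 1) * s / 2 for n, s in zip(shape, spacing)))
    return VolumetricImage(grid=grid, voxels=values, unit=IntensityUnit.DENSITY,
                           padding_value=0.0)


class TestWeplAlongRay:
    def test_uniform_water_closed_form(self):
        rho = _density_image(np.ones((5, 5, 101)))  # 100 mm of water along z
        entry = rho.grid.index_to_world(np.array([2.0, 2.0, 0.0]))
        w = wepl_along_ray(rho, entry, (0.0, 0.0, 1.0), step_mm=0.5)
        assert w == pytest.approx(100.0, rel=1e-6)

    def test_water_plus_lung_closed_form(self):
        vals = np.ones((5, 5, 101))
        vals[:, :, 40:] = 0.25  # 40 mm water then ~60 mm lung
        rho = _density_image(vals)
        entry = rho.grid.index_to_world(np.array([2.0, 2.0, 0.0]))
        w = wepl_along_ray(rho, entry, (0.0, 0.0, 1.0), step_mm=0.25)
        # interface partial volume spans one voxel: tolerance half a step
        assert w == pytest.approx(40.0 * 1.0 + 60.0 * 0.25, abs=0.5)

    def test_oblique_ray_converges_under_step_halving(self, phantom0):
        ct, _ = phantom0
        rho = hu_to_density(ct)
        entry = np.array([-120.0, -90.0, -40.0])
        direction = np.array([0.5, 0.8, 0.33])
        direction /= np.linalg.norm(direction)
        coarse = wepl_along_ray(rho, entry, direction, step_mm=1.0)
        fine = wepl_along_ray(rho, entry, direction, step_mm=0.5)
        finest = wepl_along_ray(rho, entry, direction, step_mm=0.05)
        assert abs(fine - finest) / finest < 0.005
        assert abs(coarse - finest) / finest < 0.01

    def test_entry_outside_grid_rejected(self):
        rho = _density_image(np.ones((5, 5, 5)))
        with pytest.raises(ValueError):
            wepl_along_ray(rho, (100.0, 0.0, 0.0), (0.0, 0.0, 1.0))


class TestWeplDiscrepancyMap:
    def _ellipsoid_pair(self, offset_hu):
        grid = ImageGrid(shape=(48, 48, 24), spacing=(2.5, 2.5, 2.5),
                         origin=(-58.75, -58.75, -28.75))
        coords = grid.world_coordinates()
        a, b, c = 45.0, 40.0, 22.0
        inside = (coords[..., 0] / a) ** 2 + (coords[..., 1] / b) ** 2 \
            + (coords[..., 2] / c) ** 2 <= 1.0
        ref = VolumetricImage(grid=grid, voxels=np.where(inside, 0.0, -1000.0))
        test = VolumetricImage(grid=grid,
                               voxels=np.where(inside, offset_hu, -1000.0))
        return ref, test, inside, (a, b, c), coords

    def test_equal_images_give_zero(self):
        ref, _, body, _, _ = self._ellipsoid_pair(0.0)
        rep = wepl_discrepancy_map(ref, ref, body)
        assert rep.max_abs_mm == 0.0

    def test_soft_offset_matches_analytic_chord(self):
        # +40 HU inside soft tissue -> density +0.02; per-ray WEPL change
        # equals 0.02 x the analytic chord length of the ellipsoid
        ref, test, body, (a, b, c), coords = self._ellipsoid_pair(40.0)
        rep = wepl_discrepancy_map(test, ref, body, ray_spacing_mm=5.0,
                                   step_mm=0.5)
        # oracle at the central ray: chord along y at x=z=0 is 2b
        central = 0.02 * 2.0 * b
        assert rep.max_abs_mm == pytest.approx(central, rel=0.02)

    def test_correction_reduces_wepl_error(self, fixture0, corrected_aligned):
        fx = fixture0
        body = fx.truth_masks.body
        rep_orig = wepl_discrepancy_map(fx.cbct_aligned, fx.ct, body)
        rep_corr = wepl_discrepancy_map(corrected_aligned.corrected, fx.ct, body)
        assert rep_corr.max_abs_mm < rep_orig.max_abs_mm

    def test_no_intersecting_rays_rejected(self):
        ref, _, _, _, _ = self._ellipsoid_pair(0.0)
        empty = np.zeros(ref.grid.shape, bool)
        with pytest.raises(ValueError):
            wepl_discrepancy_map(ref, ref, empty)
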