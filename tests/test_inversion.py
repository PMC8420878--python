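import numpy as np
import pytest

from hsicurve.datacube import ReflectanceCube
from hsicurve.inversion import (
    FitConfig,
    ForwardModel,
    fit_cube,
    fit_spectrum,
    max_valid_angle,
    multistart_init,
    radial_average,
)


@pytest.fixture(scope="module")
def phantom_cfg():
    return FitConfig(model="phantom", seed=42, max_iterations=60)


class TestFitSpectrum:
    def test_fixed_point_converges_immediately(self, fm_phantom, phantom_cfg):
        truth = np.array([3.7, 1.6])
        spec = fm_phantom.reflectance(truth)
        fr = fit_spectrum(spec, fm_phantom, phantom_cfg, init=truth)
        assert fr.converged
        assert fr.n_iter <= 6  # residual already zero at the start
        assert np.allclose(fr.params, truth, rtol=1e-6)
        assert fr.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_recovery_from_default_init(self, fm_phantom, phantom_cfg):
        truth = np.array([12.0, 4.2])
        spec = fm_phantom.reflectance(truth)
        fr = fit_spectrum(spec, fm_phantom, phantom_cfg)  # mid-bounds start
        assert np.all(np.abs(fr.params / truth - 1) < 0.01)

    def test_cosine_scaled_spectrum_biases_absorption_high(self, fm_phantom, phantom_cfg):
        # an uncorrected 60-degree tilt halves the spectrum; the fit explains
        # the missing light as extra absorption
        truth = np.array([3.7, 1.6])
        spec = fm_phantom.reflectance(truth) * 0.5
        fr = fit_spectrum(spec, fm_phantom, phantom_cfg, init=truth)
        assert fr.params[0] > truth[0] * 1.2

    def test_out_of_bounds_truth_lands_on_bound_with_flag(self, fm_phantom, phantom_cfg):
        spec = fm_phantom.reflectance(np.array([3.7, 1.6])) * 0.12
        fr = fit_spectrum(spec, fm_phantom, phantom_cfg, init=np.array([30.0, 1.0]))
        assert fr.at_bound.any()

    def test_nonfinite_spectrum_fails_gracefully(self, fm_phantom, phantom_cfg):
        spec = np.full(fm_phantom.grid.size, np.nan)
        fr = fit_spectrum(spec, fm_phantom, phantom_cfg)
        assert not fr.converged
        assert np.all(np.isnan(fr.params))

    def test_resampling_from_native_grid(self, fm_phantom, phantom_cfg):
        truth = np.array([5.0, 2.0])
        fine = np.arange(430.0, 701.0, 1.0)
        fm_fine = ForwardModel("phantom", fine)
        spec_fine = fm_fine.reflectance(truth)
        fr = fit_spectrum(spec_fine, fm_phantom, phantom_cfg, init=truth * 2,
                          measured_wavelengths=fine)
        assert np.all(np.abs(fr.params / truth - 1) < 0.01)


class TestMultistart:
    def test_single_start_is_single_seeded_fit(self, fm_phantom):
        cfg = FitConfig(model="phantom", seed=9, n_starts=1, max_iterations=60)
        spec = fm_phantom.reflectance(np.array([8.0, 3.0]))
        p1 = multistart_init(spec[None, :], fm_phantom, cfg)
        rng = np.random.default_rng(9)
        lo = np.array([0.1, 0.1])
        hi = np.array([45.0, 10.0])
        draw = lo + (hi - lo) * rng.random((1, 2))
        fr = fit_spectrum(spec, fm_phantom, cfg, init=draw[0])
        assert np.allclose(p1, fr.params, rtol=1e-9)

    def test_recovers_truth_within_2pct(self, fm_phantom):
        cfg = FitConfig(model="phantom", seed=4, n_starts=24, max_iterations=60)
        truth = np.array([14.0, 5.0])
        region = np.tile(fm_phantom.reflectance(truth), (4, 1))
        best = multistart_init(region, fm_phantom, cfg)
        assert np.all(np.abs(best / truth - 1) < 0.02)

    def test_same_seed_same_output(self, fm_phantom):
        cfg = FitConfig(model="phantom", seed=77, n_starts=6, max_iterations=40)
        spec = fm_phantom.reflectance(np.array([6.0, 2.0]))
        a = multistart_init(spec[None, :], fm_phantom, cfg)
        b = multistart_init(spec[None, :], fm_phantom, cfg)
        assert np.array_equal(a, b)

    def test_no_valid_spectra_raises(self, fm_phantom, phantom_cfg):
        with pytest.raises(ValueError):
            multistart_init(np.full((2, fm_phantom.grid.size), np.nan), fm_phantom, phantom_cfg)


class TestFitCube:
    def test_homogeneous_cube_gives_flat_maps(self, fm_phantom):
        cfg = FitConfig(model="phantom", seed=1, n_starts=8, max_iterations=60,
                        spatial_binning=1, spectral_binning=1, init_region_size=2)
        truth = np.array([3.7, 1.6])
        spec = fm_phantom.reflectance(truth)
        vals = np.tile(spec, (3, 4, 1))
        cube = ReflectanceCube(values=vals, wavelengths=fm_phantom.grid)
        pm = fit_cube(cube, fm_phantom, cfg)
        assert pm.valid.all()
        for k, t in zip(("Cabs", "Csc"), truth):
            assert np.nanstd(pm.params[k]) < 0.01 * t
            assert np.allclose(pm.params[k], t, rtol=0.01)

    def test_invalid_pixels_skipped(self, fm_phantom):
        cfg = FitConfig(model="phantom", seed=1, n_starts=4, max_iterations=40,
                        spatial_binning=1, spectral_binning=1, init_region_size=2)
        spec = fm_phantom.reflectance(np.array([3.7, 1.6]))
        vals = np.tile(spec, (2, 2, 1))
        mask = np.array([[True, False], [True, True]])
        cube = ReflectanceCube(values=vals, wavelengths=fm_phantom.grid, valid_mask=mask)
        pm = fit_cube(cube, fm_phantom, cfg)
        assert not pm.valid[0, 1]
        assert np.isnan(pm.params["Cabs"][0, 1])

    def test_deterministic_given_seed(self, fm_phantom):
        cfg = FitConfig(model="phantom", seed=5, n_starts=4, max_iterations=40,
                        spatial_binning=1, spectral_binning=1, init_region_size=2)
        spec = fm_phantom.reflectance(np.array([6.0, 3.0]))
        cube = ReflectanceCube(values=np.tile(spec, (2, 2, 1)), wavelengths=fm_phantom.grid)
        a = fit_cube(cube, fm_phantom, cfg)
        b = fit_cube(cube, fm_phantom, cfg)
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k], equal_nan=True)


class TestMapMetrics:
    def test_radial_average_of_constant_map(self):
        vals = np.full((11, 11), 3.0)
        r, mean, sd, cnt = radial_average(vals, (5, 5), n_bins=5)
        present = cnt > 0
        assert np.allclose(mean[present], 3.0)
        assert np.allclose(sd[present], 0.0)

    def test_radial_average_matches_analytic_profile(self):
        ii, jj = np.mgrid[0:41, 0:41]
        r = np.hypot(ii - 20, jj - 20)
        vals = 2.0 + 0.1 * r
        centers, mean, _, cnt = radial_average(vals, (20, 20), n_bins=10, r_max=20.0)
        sel = cnt > 20
        assert np.allclose(mean[sel], 2.0 + 0.1 * centers[sel], atol=0.05)

    def test_symmetric_map_has_zero_sd(self):
        ii, jj = np.mgrid[0:21, 0:21]
        r2 = (ii - 10.0) ** 2 + (jj - 10.0) ** 2
        vals = np.exp(-r2 / 50.0)
        _, _, sd, cnt = radial_average(vals, (10, 10), n_bins=40)
        assert np.nanmax(sd[cnt > 0]) < 0.02

    def test_max_valid_angle_constant_map(self):
        vals = np.full((21, 21), 1.0)
        ii, jj = np.mgrid[0:21, 0:21]
        theta = np.hypot(ii - 10, jj - 10) * 5.0
        angle = max_valid_angle(vals, theta, (10, 10), n_bins=10)
        assert angle == pytest.approx(np.nanmax(
            radial_average(theta, (10, 10), n_bins=10)[1]), abs=1e-9)

    def test_max_valid_angle_step_deviation(self):
        ii, jj = np.mgrid[0:41, 0:41]
        r = np.hypot(ii - 20, jj - 20)
        theta = np.clip(r * 3.0, 0, 90)  # 3 deg per pixel radius
        vals = np.where(theta <= 30.0, 1.0, 1.2)  # 20% step beyond 30 deg
        angle = max_valid_angle(vals, theta, (20, 20), tol=0.05, n_bins=30)
        assert 24.0 <= angle <= 31.0

    def test_max_valid_angle_immediate_deviation_returns_zero(self):
        ii, jj = np.mgrid[0:21, 0:21]
        r = np.hypot(ii - 10, jj - 10)
        vals = 1.0 + r  # deviates immediately
        theta = r * 5.0
        assert max_valid_angle(vals, theta, (10, 10), tol=0.05, central_value=1.0) <= 5.0
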