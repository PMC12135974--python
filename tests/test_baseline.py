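"""Baseline models: constant correction, Fresnel/Cauchy, scattering fits."""

import numpy as np
import pytest

import icospec as ic
from icospec.baseline import BaselineFit


class TestConstantBaseline:
    def test_flat_spectrum_goes_to_zero(self, flat_spectrum):
        out = ic.constant_baseline_correct(flat_spectrum, (650, 700))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_band_mean_zero_after_correction(self, peak_spectrum):
        out = ic.constant_baseline_correct(peak_spectrum, (650, 700))
        idx = out.band_indices((650, 700))
        assert abs(np.mean(out.values[idx])) < 1e-12

    def test_idempotent(self, peak_spectrum):
        once = ic.constant_baseline_correct(peak_spectrum, (650, 700))
        twice = ic.constant_baseline_correct(once, (650, 700))
        np.testing.assert_allclose(once.values, twice.values, atol=1e-14)

    def test_masked_points_ignored_in_band_mean(self, grid):
        vals = np.full(grid.size, 0.2)
        mask = np.zeros(grid.size, bool)
        idx = np.nonzero((grid >= 650) & (grid <= 700))[0]
        vals[idx[0]] = 100.0  # huge outlier, masked
        mask[idx[0]] = True
        s = ic.Spectrum(grid, vals, mask=mask)
        out = ic.constant_baseline_correct(s, (650, 700))
        np.testing.assert_allclose(out.values[~out.mask], 0.0, atol=1e-12)

    def test_band_outside_grid_raises(self, peak_spectrum):
        with pytest.raises(ValueError):
            ic.constant_baseline_correct(peak_spectrum, (900, 950))


class TestFresnelCauchy:
    def test_equal_indices_no_reflection(self):
        assert ic.fresnel_reflectivity(1.4, 1.4) == 0.0

    def test_symmetry(self):
        assert ic.fresnel_reflectivity(1.0, 1.5) == pytest.approx(
            ic.fresnel_reflectivity(1.5, 1.0))

    def test_air_glass_value(self):
        # ((1.0 - 1.5) / (1.0 + 1.5))^2 = 0.04
        assert ic.fresnel_reflectivity(1.0, 1.5) == pytest.approx(0.04)

    def test_nonpositive_index_rejected(self):
        with pytest.raises(ValueError):
            ic.fresnel_reflectivity(0.0, 1.5)

    def test_cauchy_constant_when_b_zero(self):
        lam = np.array([300.0, 500.0, 800.0])
        np.testing.assert_allclose(ic.cauchy_index(1.33, 0.0, lam), 1.33)

    def test_cauchy_water_like_value(self):
        # 1.33 + 3000 / 500^2 = 1.342
        assert ic.cauchy_index(1.33, 3000.0, 500.0) == pytest.approx(1.342)

    def test_cauchy_decreasing_for_positive_b(self):
        lam = np.linspace(300, 800, 50)
        n = ic.cauchy_index(1.33, 3000.0, lam)
        assert np.all(np.diff(n) < 0)

    def test_cauchy_rejects_nonpositive_wavelength(self):
        with pytest.raises(ValueError):
            ic.cauchy_index(1.33, 3000.0, 0.0)


class TestScatteringFit:
    def test_rayleigh_parameter_recovery(self, grid, baseline_segments):
        s = ic.Spectrum(grid, 2e9 / grid**4 + 0.05)
        fit = ic.fit_scattering_baseline(s, baseline_segments,
                                         variant="rayleigh_only")
        assert fit.params["e"] == pytest.approx(2e9, rel=1e-3)
        assert fit.const == pytest.approx(0.05, abs=1e-4)

    def test_power_law_recovery_with_free_exponent(self, grid,
                                                   baseline_segments):
        s = ic.Spectrum(grid, 5e5 * grid**-2.5 + 0.02)
        fit = ic.fit_scattering_baseline(s, baseline_segments,
                                         variant="power_law")
        assert fit.params["n"] == pytest.approx(2.5, rel=1e-3)
        assert fit.params["e"] == pytest.approx(5e5, rel=1e-3)

    def test_power_law_fixed_exponent(self, grid, baseline_segments):
        s = ic.Spectrum(grid, 5e5 * grid**-2.5 + 0.02)
        fit = ic.fit_scattering_baseline(s, baseline_segments,
                                         variant="power_law", power_n=2.5)
        assert fit.params["n"] == 2.5
        assert fit.params["e"] == pytest.approx(5e5, rel=1e-3)

    def test_fresnel_curve_recovery(self, fresnel_truth, baseline_segments):
        """The evaluated baseline matches truth within 1% of peak amplitude."""
        spectrum, truth, _ = fresnel_truth
        fit = ic.fit_scattering_baseline(spectrum, baseline_segments,
                                         variant="fresnel_rayleigh")
        grid = spectrum.wavelengths
        sel = (grid >= 350) & (grid <= 750)
        err = np.max(np.abs(fit.evaluate(grid[sel]) - truth[sel]))
        assert err < 0.01 * 0.8  # 1% of the 0.8 OD main peak

    def test_rayleigh_400_800_ratio(self):
        fit = BaselineFit(variant="rayleigh_only", params={"e": 2e9},
                          const=0.0, segment_rms=[])
        ratio = fit.evaluate(np.array([400.0]))[0] / fit.evaluate(
            np.array([800.0]))[0]
        assert ratio == pytest.approx(16.0, abs=1e-6)

    def test_constant_shift_absorbed_by_const(self, grid, baseline_segments):
        s1 = ic.Spectrum(grid, 2e9 / grid**4 + 0.05)
        s2 = ic.Spectrum(grid, 2e9 / grid**4 + 0.35)
        f1 = ic.fit_scattering_baseline(s1, baseline_segments, "rayleigh_only")
        f2 = ic.fit_scattering_baseline(s2, baseline_segments, "rayleigh_only")
        assert f1.params["e"] == pytest.approx(f2.params["e"], rel=1e-6)
        assert f2.const - f1.const == pytest.approx(0.3, abs=1e-6)

    def test_huge_divergence_removes_segment(self, grid):
        """A segment with divergence 1e6 has negligible influence."""
        rng = np.random.default_rng(5)
        vals = 2e9 / grid**4 + 0.05
        # corrupt the mid segment so its influence would be visible
        mid = (grid >= 480) & (grid <= 520)
        vals = vals + np.where(mid, 0.5, 0.0)
        s = ic.Spectrum(grid, vals)
        cfg3 = ic.SegmentConfig(segments=[(320, 360), (480, 520), (680, 780)],
                                divergence=[1.0, 1e6, 1.0])
        cfg2 = ic.SegmentConfig(segments=[(320, 360), (680, 780)])
        f3 = ic.fit_scattering_baseline(s, cfg3, "rayleigh_only")
        f2 = ic.fit_scattering_baseline(s, cfg2, "rayleigh_only")
        assert f3.params["e"] == pytest.approx(f2.params["e"], abs=1e-6 * 2e9)
        assert f3.const == pytest.approx(f2.const, abs=1e-6)

    def test_offset_fraction_lowers_fit(self, grid, baseline_segments):
        """The offset forces the fitted curve below the observed segments."""
        s = ic.Spectrum(grid, 2e9 / grid**4 + 0.05
                        + 0.8 * np.exp(-0.5 * ((grid - 430) / 18) ** 2))
        cfg = ic.SegmentConfig(segments=[(320, 360), (480, 520), (680, 780)],
                               offset_fraction=0.05)
        fit = ic.fit_scattering_baseline(s, cfg, "rayleigh_only",
                                         max_peak_band=(410, 450))
        plain = ic.SegmentConfig(
            segments=[(320, 360), (480, 520), (680, 780)])
        fit0 = ic.fit_scattering_baseline(s, plain, "rayleigh_only")
        peak = float(np.max(s.values[s.band_indices((410, 450))]))
        assert fit.const == pytest.approx(fit0.const - 0.05 * peak, abs=1e-6)

    def test_nonnegative_evaluate_for_fresnel(self, fresnel_truth,
                                              baseline_segments):
        spectrum, _, _ = fresnel_truth
        fit = ic.fit_scattering_baseline(spectrum, baseline_segments,
                                         variant="fresnel_rayleigh")
        fit.const = max(fit.const, 0.0)
        assert np.all(fit.evaluate(spectrum.wavelengths) >= 0.0)

    def test_degenerate_segment_rejected(self, grid):
        with pytest.raises(ValueError):
            cfg = ic.SegmentConfig(segments=[(400.0, 400.2)])
            s = ic.Spectrum(grid, np.ones(grid.size))
            ic.fit_scattering_baseline(s, cfg, "rayleigh_only")


class TestSubtractBaseline:
    def test_pure_baseline_residual_below_noise(self, grid,
                                                baseline_segments):
        rng = np.random.default_rng(6)
        sigma = 0.002
        truth = 2e9 / grid**4 + 0.05
        s = ic.Spectrum(grid, truth + sigma * rng.standard_normal(grid.size))
        fit = ic.fit_scattering_baseline(s, baseline_segments,
                                         "rayleigh_only")
        out = ic.subtract_baseline(s, fit)
        idx = np.concatenate([out.band_indices(seg)
                              for seg in baseline_segments.segments])
        assert np.sqrt(np.mean(out.values[idx] ** 2)) < sigma

    def test_refit_after_subtraction_is_null(self, grid, baseline_segments):
        s = ic.Spectrum(grid, 2e9 / grid**4 + 0.05)
        fit = ic.fit_scattering_baseline(s, baseline_segments,
                                         "rayleigh_only")
        out = ic.subtract_baseline(s, fit)
        refit = ic.fit_scattering_baseline(out, baseline_segments,
                                           "rayleigh_only")
        assert abs(refit.params["e"]) < 1e-3 * 2e9
        assert abs(refit.const) < 1e-6

    def test_masked_points_stay_masked(self, grid, baseline_segments):
        mask = np.zeros(grid.size, bool)
        mask[[7, 8]] = True
        s = ic.Spectrum(grid, 2e9 / grid**4 + 0.05, mask=mask)
        fit = ic.fit_scattering_baseline(s, baseline_segments,
                                         "rayleigh_only")
        out = ic.subtract_baseline(s, fit)
        assert out.mask[7] and out.mask[8]

    def test_history_updated(self, grid, baseline_segments):
        s = ic.Spectrum(grid, 2e9 / grid**4 + 0.05)
        fit = ic.fit_scattering_baseline(s, baseline_segments,
                                         "rayleigh_only")
        out = ic.subtract_baseline(s, fit)
        assert out.history[-1]["op"] == "subtract_baseline"
        assert out.history[-1]["variant"] == "rayleigh_only"
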