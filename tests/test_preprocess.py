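"""Smoothing filters, peak scaling and difference spectra."""

import numpy as np
import pytest

import icospec as ic


def _uniform_spectrum(values):
    grid = 300.0 + 0.5 * np.arange(len(values))
    return ic.Spectrum(grid, np.asarray(values, float))


def brute_force_savgol(values, i, window, degree):
    """Independent oracle: plain least-squares polynomial over the point's
    (boundary-clamped) window, evaluated at the point's position."""
    half = window // 2
    start = min(max(i - half, 0), len(values) - window)
    win = values[start:start + window]
    x = np.arange(window, dtype=float)
    coeffs = np.polynomial.polynomial.polyfit(x, win, degree)
    return np.polynomial.polynomial.polyval(float(i - start), coeffs)


class TestSavgol:
    def test_constant_preserved(self):
        s = _uniform_spectrum(np.full(100, 0.7))
        out = ic.smooth_savgol(s)
        np.testing.assert_allclose(out.values, 0.7, atol=1e-12)

    def test_cubic_preserved_exactly(self):
        grid = np.linspace(0, 1, 120)
        s = ic.Spectrum(300 + grid * 100, grid**3 - 0.4 * grid)
        out = ic.smooth_savgol(s, window=21, degree=3)
        np.testing.assert_allclose(out.values, s.values, atol=1e-9)

    def test_matches_brute_force_window_fit(self):
        rng = np.random.default_rng(11)
        vals = np.cumsum(rng.standard_normal(200)) * 0.01
        s = _uniform_spectrum(vals)
        out = ic.smooth_savgol(s, window=21, degree=3)
        for i in [0, 1, 10, 57, 100, 198, 199]:
            expect = brute_force_savgol(vals, i, 21, 3)
            assert out.values[i] == pytest.approx(expect, abs=1e-9)

    def test_linearity(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(150)
        y = rng.standard_normal(150)
        sx = ic.smooth_savgol(_uniform_spectrum(x))
        sy = ic.smooth_savgol(_uniform_spectrum(y))
        combo = ic.smooth_savgol(_uniform_spectrum(2.0 * x - 3.0 * y))
        np.testing.assert_allclose(combo.values,
                                   2.0 * sx.values - 3.0 * sy.values,
                                   atol=1e-12)

    def test_masked_points_excluded_and_stay_masked(self):
        rng = np.random.default_rng(13)
        vals = rng.standard_normal(100) * 0.01 + 1.0
        grid = 300.0 + 0.5 * np.arange(100)
        mask = np.zeros(100, bool)
        mask[50] = True
        vals_spiked = vals.copy()
        vals_spiked[50] = 1e6  # masked outlier must not leak into windows
        s = ic.Spectrum(grid, vals_spiked, mask=mask)
        out = ic.smooth_savgol(s)
        assert out.mask[50]
        assert np.all(np.abs(out.values[~out.mask]) < 10.0)

    def test_window_too_large_rejected(self):
        s = _uniform_spectrum(np.ones(15))
        with pytest.raises(ValueError):
            ic.smooth_savgol(s, window=21)

    def test_even_window_rejected(self):
        s = _uniform_spectrum(np.ones(100))
        with pytest.raises(ValueError):
            ic.smooth_savgol(s, window=20)


class TestRolling:
    def test_window_one_is_identity(self):
        rng = np.random.default_rng(14)
        s = _uniform_spectrum(rng.standard_normal(50))
        out = ic.smooth_rolling(s, window=1)
        np.testing.assert_array_equal(out.values, s.values)

    def test_constant_unchanged(self):
        s = _uniform_spectrum(np.full(60, 0.3))
        out = ic.smooth_rolling(s, window=9)
        np.testing.assert_allclose(out.values, 0.3, atol=1e-12)

    def test_full_window_on_ramp_matches_padded_mean(self):
        n = 21
        vals = np.linspace(0.0, 1.0, n)
        out = ic.smooth_rolling(_uniform_spectrum(vals), window=n)
        # direct computation: centred window over the mirror-padded ramp
        half = (n - 1) // 2
        padded = np.concatenate([vals[half:0:-1], vals, vals[-2:-half - 2:-1]])
        expect = [padded[i:i + n].mean() for i in range(n)]
        np.testing.assert_allclose(out.values, expect, atol=1e-12)
        # the centre point sees the whole ramp: exactly the global mean
        assert out.values[half] == pytest.approx(0.5, abs=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(15)
        x, y = rng.standard_normal(80), rng.standard_normal(80)
        sx = ic.smooth_rolling(_uniform_spectrum(x), 7)
        sy = ic.smooth_rolling(_uniform_spectrum(y), 7)
        combo = ic.smooth_rolling(_uniform_spectrum(x + 2 * y), 7)
        np.testing.assert_allclose(combo.values, sx.values + 2 * sy.values,
                                   atol=1e-12)

    def test_invalid_window(self):
        s = _uniform_spectrum(np.ones(10))
        with pytest.raises(ValueError):
            ic.smooth_rolling(s, window=0)


class TestScaleToPeak:
    def test_scaling_to_current_max_is_identity(self, peak_spectrum):
        peak = float(np.max(peak_spectrum.values))
        out = ic.scale_to_peak(peak_spectrum, (410, 450), target=peak)
        np.testing.assert_allclose(out.values, peak_spectrum.values,
                                   atol=1e-12)

    def test_scale_invariance(self, peak_spectrum):
        a = peak_spectrum.with_values(peak_spectrum.values * 2.0)
        b = peak_spectrum.with_values(peak_spectrum.values * 5.0)
        ua = ic.scale_to_peak(a, (410, 450), target="unit")
        ub = ic.scale_to_peak(b, (410, 450), target="unit")
        np.testing.assert_allclose(ua.values, ub.values, atol=1e-12)

    def test_unit_target_idempotent(self, peak_spectrum):
        once = ic.scale_to_peak(peak_spectrum, (410, 450), target="unit")
        twice = ic.scale_to_peak(once, (410, 450), target="unit")
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_doubling(self, grid):
        vals = 0.5 * np.exp(-0.5 * ((grid - 430) / 18) ** 2)
        s = ic.Spectrum(grid, vals)
        out = ic.scale_to_peak(s, (410, 450), target=1.0)
        np.testing.assert_allclose(out.values, 2.0 * vals, atol=1e-12)

    def test_nonpositive_peak_advises_baseline(self, grid):
        s = ic.Spectrum(grid, np.full(grid.size, -0.1))
        with pytest.raises(ValueError, match="baseline"):
            ic.scale_to_peak(s, (410, 450))


class TestDifferenceSeries:
    def test_dark_equals_first_member(self, br):
        series, _ = br
        diff = ic.difference_series(series, series[0])
        np.testing.assert_allclose(diff[0].values, 0.0, atol=1e-12)

    def test_identical_members_all_zero(self, grid):
        members = [ic.Spectrum(grid, np.ones(grid.size), label=float(i))
                   for i in range(4)]
        series = ic.SpectrumSeries(members, axis="time")
        diff = ic.difference_series(series, members[0])
        for m in diff:
            np.testing.assert_allclose(m.values, 0.0, atol=1e-12)

    def test_m_state_sign_pattern(self, br):
        """Positive difference near 400 nm, negative near 600 nm while the
        blue-shifted intermediate is populated."""
        series, _ = br
        diff = ic.difference_series(series, series[0])
        mid = diff[6]  # 3 ms: intermediate occupied, ground depleted
        grid = diff.wavelengths
        assert mid.values[np.argmin(np.abs(grid - 400))] > 0.05
        assert mid.values[np.argmin(np.abs(grid - 600))] < -0.05

    def test_mask_union_propagates(self, grid):
        m0 = np.zeros(grid.size, bool)
        m0[5] = True
        dark = ic.Spectrum(grid, np.zeros(grid.size), mask=m0)
        m1 = np.zeros(grid.size, bool)
        m1[9] = True
        member = ic.Spectrum(grid, np.ones(grid.size), label=1.0, mask=m1)
        series = ic.SpectrumSeries([member], axis="time")
        diff = ic.difference_series(series, dark)
        assert diff[0].mask[5] and diff[0].mask[9]

    def test_grid_mismatch_rejected(self, grid):
        series = ic.SpectrumSeries(
            [ic.Spectrum(grid, np.ones(grid.size), label=0.0)], axis="index")
        other = ic.Spectrum(grid[:-10], np.ones(grid.size - 10))
        with pytest.raises(ic.GridMismatchError):
            ic.difference_series(series, other)
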