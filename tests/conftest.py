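"""Shared fixtures: synthetic spectra and series with known ground truth."""

import numpy as np
import pytest

import icospec as ic
from icospec.synthetic import default_grid


@pytest.fixture
def grid():
    return default_grid(320.0, 780.0, 0.5)


@pytest.fixture
def flat_spectrum(grid):
    return ic.Spectrum(grid, np.full(grid.size, 0.25))


@pytest.fixture
def peak_spectrum(grid):
    """Gaussian band at 430 nm on a 0.1 OD offset — no scattering."""
    vals = 0.1 + 0.8 * np.exp(-0.5 * ((grid - 430.0) / 18.0) ** 2)
    return ic.Spectrum(grid, vals)


@pytest.fixture
def fresnel_truth(grid):
    """Known fresnel_rayleigh baseline plus two Gaussian peaks."""
    a, b, c, d, e = 1.33, 3000.0, 1.50, 4200.0, 2e9
    n1 = a + b / grid**2
    n2 = c + d / grid**2
    baseline = ((n1 - n2) / (n1 + n2)) ** 2 + e / grid**4
    peaks = (0.8 * np.exp(-0.5 * ((grid - 430.0) / 18.0) ** 2)
             + 0.35 * np.exp(-0.5 * ((grid - 600.0) / 25.0) ** 2))
    spectrum = ic.Spectrum(grid, baseline + peaks)
    return spectrum, baseline, {"a": a, "b": b, "c": c, "d": d, "e": e}


@pytest.fixture
def baseline_segments():
    """Three non-absorbing segments avoiding the 430/600 nm peaks."""
    return ic.SegmentConfig(segments=[(320.0, 360.0), (480.0, 520.0),
                                      (680.0, 780.0)])


@pytest.fixture
def br():
    """Noise-free bacteriorhodopsin-like series with its dent-free twin."""
    _, series = ic.br_series(seed=1, noise=0.0)
    _, clean = ic.br_series(seed=1, noise=0.0, dent_depth=0.0)
    return series, clean
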