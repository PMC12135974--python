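"""Smoothing, peak scaling, and difference-spectrum construction.

Both smoothers are linear operators that keep the spectrum's length.
The Savitzky–Golay filter defaults to a third-degree polynomial over
21-point windows — it preserves peak positions and widths far better
than a plain rolling mean, which is kept as the simple alternative.
Savitzky–Golay edges are handled by fitting the polynomial to the first
and last full windows and evaluating it off-centre, so polynomials up to
the filter degree pass through the filter *exactly*, edges included; the
rolling mean uses mirror-padded edges.

Masked points are excluded from every window: the output at a clean
point comes from a local least-squares re-fit on the remaining window
points (if enough survive for the polynomial degree), and a masked point
stays masked.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import savgol_filter

from .core import GridMismatchError, Spectrum, SpectrumSeries

__all__ = [
    "smooth_savgol",
    "smooth_rolling",
    "scale_to_peak",
    "difference_series",
]


def _check_uniform(wavelengths: np.ndarray) -> None:
    dw = np.diff(wavelengths)
    spread = (dw.max() - dw.min()) / dw.mean()
    if spread > 0.05:
        warnings.warn(
            f"wavelength spacing varies by {spread:.1%}; smoothing windows "
            "assume an approximately uniform grid", stacklevel=3)


def smooth_savgol(s: Spectrum, window: int = 21, degree: int = 3) -> Spectrum:
    """Savitzky–Golay smoothing (degree-3 / 21-point defaults).

    Each point is replaced by the value of the least-squares polynomial
    of ``degree`` fitted over its ``window`` neighbours (evaluated at the
    window centre for interior points and off-centre within the first or
    last full window at the edges).  Polynomials up to ``degree`` are
    reproduced exactly on a uniform grid.
    """
    if window % 2 == 0 or window <= degree:
        raise ValueError("window must be odd and larger than degree")
    if window >= len(s):
        raise ValueError(f"window {window} must be smaller than the "
                         f"spectrum length {len(s)}")
    _check_uniform(s.wavelengths)
    if not s.mask.any():
        out = savgol_filter(s.values, window, degree, mode="interp")
        return s.with_values(out, op="smooth_savgol", window=window,
                             degree=degree)
    out, new_mask = _masked_polyfit_smooth(s.values, s.mask, window, degree)
    return s.with_values(out, op="smooth_savgol", window=window, degree=degree,
                         mask=new_mask)


def _masked_polyfit_smooth(values, mask, window, degree):
    """Per-window polynomial re-fit skipping masked points.

    Windows are clamped at the boundaries (matching savgol's ``interp``
    edge handling) and the polynomial is evaluated at the point's offset
    within its window.
    """
    half = window // 2
    n = values.size
    out = np.full(n, np.nan)
    for i in range(n):
        if mask[i]:
            continue
        start = min(max(i - half, 0), n - window)
        sl = slice(start, start + window)
        keep = ~mask[sl]
        x = np.arange(window, dtype=float) - half
        if keep.sum() >= degree + 2:
            coeffs = np.polynomial.polynomial.polyfit(
                x[keep], values[sl][keep], degree)
            out[i] = np.polynomial.polynomial.polyval(
                float(i - start - half), coeffs)
        # else: insufficient support, point stays NaN/masked
    new_mask = mask | ~np.isfinite(out)
    return np.where(np.isfinite(out), out, 0.0), new_mask


def smooth_rolling(s: Spectrum, window: int) -> Spectrum:
    """Centred moving mean with mirror-padded edges, masked-aware."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(s):
        raise ValueError("window exceeds the spectrum length")
    if window == 1:
        return s.with_values(s.values, op="smooth_rolling", window=1)
    # use a symmetric window of odd effective size: pad by half each side
    half = (window - 1) // 2
    right = window - 1 - half
    v = np.where(s.mask, np.nan, s.values)
    pad_l = v[half:0:-1] if half else np.empty(0)
    pad_r = v[-2:-right - 2:-1] if right else np.empty(0)
    vp = np.concatenate([pad_l, v, pad_r])
    valid = np.isfinite(vp).astype(float)
    vp0 = np.where(np.isfinite(vp), vp, 0.0)
    kernel = np.ones(window)
    sums = np.convolve(vp0, kernel, mode="valid")
    counts = np.convolve(valid, kernel, mode="valid")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out = np.where(counts > 0, out, np.nan)
    new_mask = s.mask | ~np.isfinite(out)
    return s.with_values(np.where(np.isfinite(out), out, 0.0),
                         op="smooth_rolling", window=window, mask=new_mask)


def scale_to_peak(s: Spectrum, peak_band: tuple[float, float],
                  target="unit") -> Spectrum:
    """Scale a spectrum so its maximum inside ``peak_band`` hits ``target``.

    Spectra from crystals of different thickness (or orientation) are
    comparable only after scaling to a conserved absorption peak; apply a
    baseline correction first so the band maximum is a real peak height.
    ``target="unit"`` normalizes the band maximum to 1.
    """
    idx = s.band_indices(peak_band)
    idx = idx[~s.mask[idx]]
    if idx.size == 0:
        raise ValueError(f"peak band {peak_band} has no valid points")
    peak = float(np.max(s.values[idx]))
    if peak <= 0:
        raise ValueError(
            f"band maximum is {peak:g} <= 0; apply a baseline correction "
            "before scaling to a peak")
    t = 1.0 if target == "unit" else float(target)
    factor = t / peak
    return s.with_values(s.values * factor, op="scale_to_peak",
                         band=[float(peak_band[0]), float(peak_band[1])],
                         factor=factor)


def difference_series(series: SpectrumSeries, dark: Spectrum) -> SpectrumSeries:
    """Light − dark difference spectra, isolating reaction-induced changes.

    The dark (ground-state) spectrum is subtracted from every member;
    labels are preserved and masks are the union of member and dark masks.
    """
    if dark.wavelengths.shape != series.wavelengths.shape or not np.allclose(
            dark.wavelengths, series.wavelengths, rtol=0, atol=1e-9):
        raise GridMismatchError("dark spectrum is not on the series grid")
    members = []
    for m in series:
        d = m.with_values(m.values - dark.values, op="difference",
                          mask=m.mask | dark.mask,
                          dark_label=dark.label)
        members.append(d)
    return SpectrumSeries(members, axis=series.axis)
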