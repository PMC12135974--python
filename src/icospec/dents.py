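"""Detection and removal of the nanosecond-laser "dent".

When the actinic nanosecond laser fires within the spectrometer's
integration window, its tail reaches the detector and carves a spurious
negative dip (a *dent*) into the absorbance spectrum at the pump
wavelength.  Smaller dips can also arise from fluorescence reaching the
downstream objective.

Detection works on the second derivative of the (Savitzky–Golay
smoothed) spectrum: candidate dips are local minima of the absorbance
with sufficient prominence, and each dip's boundaries are the nearest
flanking zero-crossings of the second derivative.  The deepest dip —
depth measured from the straight line joining its boundary points down
to its minimum — is taken as the laser contribution; the rest are
catalogued as minor dips.  Within a kinetic series the laser wavelength
is fixed, so later members are searched only inside the first member's
dent interval (slightly widened), and their dent points are likewise
removed.

"Removed" means masked (grid-preserving) or linearly interpolated across
the dent interval, at the caller's choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .core import Spectrum, SpectrumSeries

__all__ = ["DentMask", "detect_dents", "remove_laser_dent"]


@dataclass
class DentMask:
    """Catalogue of absorption dips found in one spectrum."""

    main_dent: tuple[float, float] | None  # (lo, hi) nm
    centre: float | None
    amplitude: float
    minor_dips: list[float] = field(default_factory=list)
    minor_amplitudes: list[float] = field(default_factory=list)
    removed_indices: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int))

    @property
    def is_empty(self) -> bool:
        return self.main_dent is None


def _robust_noise_sigma(values: np.ndarray) -> float:
    """Noise scale from the median absolute successive difference."""
    d = np.diff(values)
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad / 0.6745 / np.sqrt(2.0)) or 1e-12


def _dip_boundaries(d2: np.ndarray, i_min: int,
                    fade: float = 0.02) -> tuple[int, int]:
    """Dip extent from the second-derivative profile around its minimum.

    A dip shows a positive-curvature core flanked by negative lobes whose
    minima mark the inflection shoulders.  The dip ends where the lobe
    curvature has faded to ``fade`` × the central curvature (the tail is
    then indistinguishable from the surrounding spectrum) or where the
    background curvature takes over (outer zero-crossing), whichever
    comes first.
    """
    n = d2.size
    c0 = d2[i_min]
    if c0 <= 0:
        # degenerate profile: fall back on the nearest zero-crossings
        lo = i_min
        while lo > 0 and not (d2[lo - 1] <= 0 <= d2[lo]):
            lo -= 1
        hi = i_min
        while hi < n - 1 and not (d2[hi] >= 0 >= d2[hi + 1]):
            hi += 1
        return lo, hi
    thr = -fade * c0

    def shoulder(direction: int) -> int:
        # nearest local minimum of d2: the dip's inflection shoulder
        i = i_min
        while 0 < i < n - 1 and d2[i] > 0:
            i += direction
        while 0 < i < n - 1 and d2[i + direction] < d2[i]:
            i += direction
        return i

    def walk(direction: int, cap: int) -> int:
        i = i_min
        while 0 < i < n - 1 and d2[i] > 0:  # leave the positive core
            i += direction
        while (0 < i < n - 1 and d2[i] < thr
               and abs(i - i_min) < cap):  # traverse the negative lobe
            i += direction
        return i

    # shoulders of a Gaussian-like dip sit at sqrt(3)·sigma from the
    # centre; 1.8× that (~3 sigma) bounds the dip so the walk cannot
    # bleed into a neighbouring absorption band's curvature
    cap_lo = max(2, int(np.ceil(1.8 * (i_min - shoulder(-1)))))
    cap_hi = max(2, int(np.ceil(1.8 * (shoulder(+1) - i_min))))
    return walk(-1, cap_lo), walk(+1, cap_hi)


def _dip_amplitude(values: np.ndarray, lo: int, hi: int, i_min: int) -> float:
    """Depth from the straight line joining the flanks down to the minimum."""
    if hi == lo:
        return 0.0
    t = (i_min - lo) / (hi - lo)
    flank = values[lo] * (1 - t) + values[hi] * t
    return float(flank - values[i_min])


def detect_dents(s: Spectrum, min_prominence: float | None = None,
                 smooth_window: int = 21,
                 search_band: tuple[float, float] | None = None) -> DentMask:
    """Locate absorption dips and single out the laser dent.

    Parameters
    ----------
    min_prominence : OD
        Minimum dip prominence; default 5 × the robust noise sigma of
        the detrended spectrum.
    smooth_window : odd int
        Window of the Savitzky–Golay differentiation (degree 3).
    search_band : optional (lo, hi) nm
        Restrict candidate minima to this interval (used when
        propagating a dent through a series).

    Returns an empty :class:`DentMask` when no dip clears the prominence
    threshold (not an error).
    """
    if len(s) <= smooth_window:
        raise ValueError("spectrum must be longer than smooth_window")
    vals = np.where(s.mask, np.nan, s.values)
    # work on an interpolated copy so masked points cannot spawn dips
    if s.mask.any():
        good = ~s.mask
        vals = np.interp(s.wavelengths, s.wavelengths[good], s.values[good])
    smoothed = savgol_filter(vals, smooth_window, 3, mode="mirror")
    d2 = savgol_filter(vals, smooth_window, 3, deriv=2, mode="mirror")
    if min_prominence is None:
        min_prominence = 5.0 * _robust_noise_sigma(vals - smoothed)

    minima, props = find_peaks(-smoothed, prominence=min_prominence)
    if search_band is not None:
        lo_nm, hi_nm = min(search_band), max(search_band)
        keep = ((s.wavelengths[minima] >= lo_nm) &
                (s.wavelengths[minima] <= hi_nm))
        minima = minima[keep]
    if minima.size == 0:
        return DentMask(main_dent=None, centre=None, amplitude=0.0)

    dips = []
    for i_min in minima:
        lo, hi = _dip_boundaries(d2, int(i_min))
        amp = _dip_amplitude(smoothed, lo, hi, int(i_min))
        dips.append((amp, int(i_min), lo, hi))
    # deepest dip wins; ties broken toward shorter wavelength
    dips.sort(key=lambda d: (-d[0], d[1]))
    amp, i_min, lo, hi = dips[0]
    removed = np.arange(lo, hi + 1)
    return DentMask(
        main_dent=(float(s.wavelengths[lo]), float(s.wavelengths[hi])),
        centre=float(s.wavelengths[i_min]),
        amplitude=amp,
        minor_dips=[float(s.wavelengths[d[1]]) for d in dips[1:]],
        minor_amplitudes=[d[0] for d in dips[1:]],
        removed_indices=removed)


def _apply_mask(s: Spectrum, mask_out: DentMask, fill: str) -> Spectrum:
    if mask_out.is_empty or mask_out.removed_indices.size == 0:
        return s.with_values(s.values, op="remove_laser_dent", removed=0)
    idx = mask_out.removed_indices
    if fill == "interpolate":
        keep = np.ones(len(s), dtype=bool)
        keep[idx] = False
        keep &= ~s.mask
        vals = s.values.copy()
        vals[idx] = np.interp(s.wavelengths[idx], s.wavelengths[keep],
                              s.values[keep])
        return s.with_values(vals, op="remove_laser_dent",
                             removed=int(idx.size), fill="interpolate",
                             interval=list(mask_out.main_dent))
    new_mask = s.mask.copy()
    new_mask[idx] = True
    return s.with_values(s.values, op="remove_laser_dent",
                         removed=int(idx.size), fill="mask",
                         interval=list(mask_out.main_dent), mask=new_mask)


def remove_laser_dent(series: SpectrumSeries,
                      template: DentMask | str = "auto",
                      fill: str = "mask",
                      min_prominence: float | None = None,
                      smooth_window: int = 21
                      ) -> tuple[SpectrumSeries, list[DentMask]]:
    """Remove the laser dent from every member of a kinetic series.

    The dent is detected on the first member (or supplied as a
    ``template``); in later members only the deepest dip inside the first
    dent's interval, widened by one smoothing window, is removed.  A
    member with no detectable dip inside that window has the template
    interval removed anyway — the laser fires on every exposure.

    Returns the corrected series and one :class:`DentMask` per member.
    """
    if fill not in ("mask", "interpolate"):
        raise ValueError("fill must be 'mask' or 'interpolate'")
    first = series[0]
    if template == "auto":
        template_mask = detect_dents(first, min_prominence=min_prominence,
                                     smooth_window=smooth_window)
    else:
        template_mask = template

    if template_mask.is_empty:
        out = [
            m.with_values(m.values, op="remove_laser_dent", removed=0)
            for m in series
        ]
        masks = [DentMask(None, None, 0.0) for _ in series]
        return SpectrumSeries(out, axis=series.axis), masks

    grid = series.wavelengths
    step = float(np.median(np.diff(grid)))
    pad = smooth_window * step
    lo, hi = template_mask.main_dent
    window_band = (lo - pad, hi + pad)

    out_members: list[Spectrum] = []
    masks: list[DentMask] = []
    for j, m in enumerate(series):
        if j == 0 and template == "auto":
            dm = template_mask
        else:
            dm = detect_dents(m, min_prominence=min_prominence,
                              smooth_window=smooth_window,
                              search_band=window_band)
            if dm.is_empty:
                # fall back on the template interval
                idx = np.nonzero((grid >= lo) & (grid <= hi))[0]
                dm = DentMask(main_dent=(lo, hi),
                              centre=template_mask.centre,
                              amplitude=0.0, removed_indices=idx)
        out_members.append(_apply_mask(m, dm, fill))
        masks.append(dm)
    return SpectrumSeries(out_members, axis=series.axis), masks
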