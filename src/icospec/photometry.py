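"""Absorbance from raw counts, and per-wavelength confidence scoring.

A microspectrophotometer records three traces: the dark counts of the
detector (lamp off), the lamp through the empty optical path, and the
light transmitted through the crystal.  Absorbance follows from the
background-subtracted transmission::

    A(λ) = -log10[ (I_sample(λ) - I_background(λ)) /
                   (I_reference(λ) - I_background(λ)) ]

Wherever a net count is non-positive the transmission is physically
meaningless, so those points are masked rather than clamped — the grid is
preserved for downstream series operations.

Low photon flux (dim lamp regions, opaque crystals) and detector
saturation both degrade the absorbance locally.  ``confidence_profile``
scores each wavelength in [0, 1] with a clipped linear ramp on the
background-subtracted counts of sample and reference, combined by
pointwise minimum, and zeroed wherever either trace saturates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GridMismatchError, RawTrace, Spectrum

__all__ = [
    "compute_absorbance",
    "detect_saturation",
    "confidence_profile",
    "ConfidenceProfile",
]

# defaults as fractions of detector full scale; conservative for
# 16-bit-like CCDs, all overridable per call
DEFAULT_LOW_FRACTION = 0.02
DEFAULT_RAMP_FRACTION = 0.08
DEFAULT_SAT_TOL_FRACTION = 0.005
DEFAULT_SAT_RUN_LENGTH = 3


@dataclass(frozen=True)
class ConfidenceProfile:
    """Per-wavelength reliability of a computed absorbance spectrum."""

    wavelengths: np.ndarray
    score: np.ndarray
    low_count_flag: np.ndarray
    saturated_flag: np.ndarray
    thresholds: dict

    def __post_init__(self):
        if np.any((self.score < 0) | (self.score > 1)):
            raise ValueError("confidence score must lie in [0, 1]")
        if np.any(self.score[self.saturated_flag] != 0):
            raise ValueError("score must be 0 wherever saturated")


def _common_grid(*traces: RawTrace) -> np.ndarray:
    grid = traces[0].wavelengths
    for t in traces[1:]:
        if t.wavelengths.shape != grid.shape or not np.allclose(
                t.wavelengths, grid, rtol=0, atol=1e-9):
            raise GridMismatchError(
                "sample, reference and background must share one grid; "
                "resample before computing absorbance")
    return grid


def compute_absorbance(sample: RawTrace, reference: RawTrace,
                       background: RawTrace) -> Spectrum:
    """Absorbance spectrum from the three raw traces.

    Points with non-positive net counts in either the numerator or the
    denominator are masked.  Raises if every point is masked.
    """
    grid = _common_grid(sample, reference, background)
    net_s = sample.counts - background.counts
    net_r = reference.counts - background.counts
    bad = (net_s <= 0) | (net_r <= 0)
    if bad.all():
        raise ValueError("no valid transmission: all net counts non-positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        a = -np.log10(np.where(bad, np.nan, net_s) / np.where(bad, np.nan, net_r))
    return Spectrum(grid, a, kind="absorbance", mask=bad,
                    history=[{"op": "compute_absorbance",
                              "masked_points": int(bad.sum())}])


def detect_saturation(trace: RawTrace, full_scale: float | str = "auto",
                      run_length: int = DEFAULT_SAT_RUN_LENGTH,
                      tol: float | None = None) -> np.ndarray:
    """Flag points sitting on a saturation plateau.

    A point is flagged iff it belongs to a run of at least ``run_length``
    consecutive points all within ``tol`` counts of ``full_scale``
    (``"auto"``: the trace maximum; ``tol`` defaults to 0.5% of it).
    """
    if run_length < 2:
        raise ValueError("run_length must be >= 2")
    fs = float(np.max(trace.counts)) if full_scale == "auto" else float(full_scale)
    if tol is None:
        tol = DEFAULT_SAT_TOL_FRACTION * fs
    if tol < 0:
        raise ValueError("tol must be >= 0")
    near = trace.counts >= fs - tol
    flags = np.zeros(len(trace), dtype=bool)
    i = 0
    n = near.size
    while i < n:
        if near[i]:
            j = i
            while j < n and near[j]:
                j += 1
            if j - i >= run_length:
                flags[i:j] = True
            i = j
        else:
            i += 1
    return flags


def confidence_profile(sample: RawTrace, reference: RawTrace,
                       background: RawTrace,
                       low: float | None = None,
                       ramp: float | None = None,
                       full_scale: float | str = "auto",
                       run_length: int = DEFAULT_SAT_RUN_LENGTH,
                       tol: float | None = None) -> ConfidenceProfile:
    """Score the reliability of each wavelength of the absorbance.

    Per trace, ``s(I) = clip((I - I_background - low) / ramp, 0, 1)``,
    zeroed on saturation plateaus; the profile score is the pointwise
    minimum over sample and reference.  ``low`` and ``ramp`` default to
    2% and 8% of full scale.
    """
    grid = _common_grid(sample, reference, background)
    fs = (max(float(np.max(sample.counts)), float(np.max(reference.counts)))
          if full_scale == "auto" else float(full_scale))
    if low is None:
        low = DEFAULT_LOW_FRACTION * fs
    if ramp is None:
        ramp = DEFAULT_RAMP_FRACTION * fs
    if ramp <= 0:
        raise ValueError("ramp must be > 0")

    def trace_score(tr: RawTrace) -> tuple[np.ndarray, np.ndarray]:
        net = tr.counts - background.counts
        s = np.clip((net - low) / ramp, 0.0, 1.0)
        sat = detect_saturation(tr, full_scale=fs, run_length=run_length, tol=tol)
        s[sat] = 0.0
        return s, sat

    s_sample, sat_sample = trace_score(sample)
    s_ref, sat_ref = trace_score(reference)
    score = np.minimum(s_sample, s_ref)
    saturated = sat_sample | sat_ref
    low_flag = ((sample.counts - background.counts <= low) |
                (reference.counts - background.counts <= low))
    return ConfidenceProfile(
        wavelengths=grid, score=score, low_count_flag=low_flag,
        saturated_flag=saturated,
        thresholds={"low": low, "ramp": ramp, "full_scale": fs,
                    "run_length": run_length,
                    "tol": DEFAULT_SAT_TOL_FRACTION * fs if tol is None else tol})
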