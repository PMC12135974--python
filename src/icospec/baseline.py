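"""Baseline models for in crystallo absorption spectra.

A single-crystal absorption spectrum rides on a non-absorbing background
made of (i) a flat offset from focal-spot displacement, (ii) reflectivity
at the crystal/mother-liquor interface and (iii) diffuse Rayleigh
scattering rising steeply to the blue.  The full model evaluated here is

    B(λ) = R(n1(λ), n2(λ)) + e / λ⁴ + const

with normal-incidence Fresnel reflectivity R = ((n1 − n2)/(n1 + n2))² of
one effective interface between two Cauchy media n_i(λ) = a_i + b_i/λ²,
giving five shape parameters a, b, c, d, e plus the constant.  Two
fallbacks cover cases where the full model misbehaves (e.g. X-ray-induced
baseline drifts): pure Rayleigh ``e/λ⁴ + const`` and a power law
``e·λ⁻ⁿ + const`` with n free in [1, 8] or user-fixed.

The parameters are fitted by weighted nonlinear least squares against the
points of up to three user-chosen non-absorbing wavelength segments
(canonically near-UV, a peakless mid region, and the red side).  Each
segment carries a positive *divergence* factor: per-point weight is
1/divergence, so a large divergence removes a segment's influence.

Note on identifiability: in the Fresnel term only the combinations
(a − c) and (b − d) enter to first order, so the individual Cauchy
coefficients are not uniquely determined by a single spectrum — the
fitted *curve* is.  Diagnostics therefore report per-segment residuals
and the evaluated baseline, not parameter uncertainties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core import FitConvergenceError, Spectrum

__all__ = [
    "SegmentConfig",
    "BaselineFit",
    "constant_baseline_correct",
    "fresnel_reflectivity",
    "cauchy_index",
    "fit_scattering_baseline",
    "subtract_baseline",
]

VARIANTS = ("fresnel_rayleigh", "rayleigh_only", "power_law")


@dataclass
class SegmentConfig:
    """Baseline-fit segments with per-segment weights and optional offset.

    Parameters
    ----------
    segments : list of (lo, hi) wavelength intervals, nm, closed and
        non-overlapping (1 to 3 of them).
    divergence : one positive factor per segment; per-point fit weight is
        1/divergence, so larger means less influence (default 1).
    offset_fraction : fraction of the maximum absorbance inside the peak
        band to subtract from the observed values of ``offset_segments``
        before fitting, forcing the fit to run below those points.
    offset_segments : indices of the segments the offset applies to
        (default: all).
    """

    segments: list[tuple[float, float]]
    divergence: list[float] | None = None
    offset_fraction: float = 0.0
    offset_segments: list[int] | None = None

    def __post_init__(self):
        if not 1 <= len(self.segments) <= 3:
            raise ValueError("need between 1 and 3 segments")
        segs = [tuple(map(float, s)) for s in self.segments]
        for lo, hi in segs:
            if hi <= lo:
                raise ValueError(f"segment [{lo}, {hi}] has hi <= lo")
        for (a_lo, a_hi), (b_lo, b_hi) in zip(sorted(segs), sorted(segs)[1:]):
            if b_lo < a_hi:
                raise ValueError("segments must not overlap")
        self.segments = segs
        if self.divergence is None:
            self.divergence = [1.0] * len(segs)
        if len(self.divergence) != len(segs):
            raise ValueError("one divergence factor per segment required")
        if any(d <= 0 for d in self.divergence):
            raise ValueError("divergence factors must be > 0")
        if self.offset_fraction < 0:
            raise ValueError("offset_fraction must be >= 0")
        if self.offset_segments is None:
            self.offset_segments = list(range(len(segs)))


@dataclass
class BaselineFit:
    """A fitted baseline: variant, parameters, and an evaluate closure."""

    variant: str
    params: dict[str, float]
    const: float
    segment_rms: list[float]
    diagnostics: dict = field(default_factory=dict)

    def evaluate(self, wavelengths: np.ndarray) -> np.ndarray:
        """Baseline OD on an arbitrary grid (nm)."""
        lam = np.asarray(wavelengths, dtype=float)
        p = self.params
        if self.variant == "fresnel_rayleigh":
            n1 = cauchy_index(p["a"], p["b"], lam)
            n2 = cauchy_index(p["c"], p["d"], lam)
            return fresnel_reflectivity(n1, n2) + p["e"] / lam**4 + self.const
        if self.variant == "rayleigh_only":
            return p["e"] / lam**4 + self.const
        if self.variant == "power_law":
            return p["e"] * lam ** (-p["n"]) + self.const
        raise ValueError(f"unknown variant {self.variant!r}")


def fresnel_reflectivity(n1, n2):
    """Normal-incidence reflectivity ((n1 − n2)/(n1 + n2))² of an interface.

    Symmetric in its arguments and always in [0, 1) for positive indices.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("refractive indices must be > 0")
    r = ((n1 - n2) / (n1 + n2)) ** 2
    return float(r) if r.ndim == 0 else r


def cauchy_index(a: float, b: float, wavelength):
    """Cauchy dispersion n(λ) = a + b/λ² (λ in nm, b in nm²)."""
    lam = np.asarray(wavelength, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be > 0")
    n = a + b / lam**2
    return float(n) if n.ndim == 0 else n


def constant_baseline_correct(s: Spectrum, band: tuple[float, float]) -> Spectrum:
    """Subtract the mean absorbance over a non-absorbing band.

    Brings spectra recorded at different focal offsets onto a common
    baseline.  Masked points inside the band are ignored; the band must
    contribute at least 3 valid points.  Idempotent.
    """
    idx = s.band_indices(band)
    if idx.size < 3:
        raise ValueError(f"band {band} covers fewer than 3 grid points")
    valid = idx[~s.mask[idx]]
    if valid.size == 0:
        raise ValueError(f"all points in band {band} are masked")
    level = float(np.mean(s.values[valid]))
    return s.with_values(s.values - level, op="constant_baseline_correct",
                         band=[float(band[0]), float(band[1])], level=level)


def _segment_points(s: Spectrum, cfg: SegmentConfig):
    """Collect (λ, value, weight, segment id) over all unmasked segment points."""
    lam, val, w, seg_id = [], [], [], []
    for k, (lo, hi) in enumerate(cfg.segments):
        idx = s.band_indices((lo, hi))
        idx = idx[~s.mask[idx]]
        if idx.size == 0:
            raise ValueError(f"segment [{lo}, {hi}] contains no valid points")
        if np.unique(s.wavelengths[idx]).size < 2:
            raise ValueError(f"segment [{lo}, {hi}] is degenerate (one wavelength)")
        lam.append(s.wavelengths[idx])
        val.append(s.values[idx])
        w.append(np.full(idx.size, 1.0 / cfg.divergence[k]))
        seg_id.append(np.full(idx.size, k))
    return (np.concatenate(lam), np.concatenate(val),
            np.concatenate(w), np.concatenate(seg_id))


def _model(variant: str, theta: np.ndarray, lam: np.ndarray) -> np.ndarray:
    if variant == "fresnel_rayleigh":
        a, b, c, d, e, const = theta
        n1 = a + b / lam**2
        n2 = c + d / lam**2
        return ((n1 - n2) / (n1 + n2)) ** 2 + e / lam**4 + const
    if variant == "rayleigh_only":
        e, const = theta
        return e / lam**4 + const
    # power_law
    e, n, const = theta
    return e * lam ** (-n) + const


def _rayleigh_prefit(lam: np.ndarray, val: np.ndarray, w: np.ndarray) -> float:
    """Weighted one-parameter λ⁻⁴ pre-fit (const at the segment minimum)."""
    x = 1.0 / lam**4
    y = val - np.min(val)
    e = float(np.sum(w * x * y) / np.sum(w * x * x))
    return max(e, 0.0)


def fit_scattering_baseline(s: Spectrum, cfg: SegmentConfig,
                            variant: str = "fresnel_rayleigh",
                            max_peak_band: tuple[float, float] | None = None,
                            power_n: float | None = None,
                            max_restarts: int = 5) -> BaselineFit:
    """Fit a scattering + reflectivity baseline to the segment points.

    Weighted nonlinear least squares over the union of the configured
    segments (per-point weight 1/divergence).  When ``offset_fraction``
    is set, that fraction of the maximum absorbance inside
    ``max_peak_band`` is first subtracted from the observed values of the
    designated segments, so the fitted curve runs below them.  Up to
    ``max_restarts`` multi-start restarts jitter the initial guess ±20%
    before the fit is declared non-convergent.

    Parameters for ``power_law``: ``power_n`` fixes the exponent;
    otherwise it is fitted within [1, 8] (hitting a bound leaves a
    warning in the diagnostics).
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    lam, val, w, seg_id = _segment_points(s, cfg)
    if lam.size < 5:
        raise ValueError("segments must contain at least 5 points in total")

    offset = 0.0
    if cfg.offset_fraction > 0:
        if max_peak_band is None:
            raise ValueError("offset_fraction > 0 requires max_peak_band")
        idx = s.band_indices(max_peak_band)
        idx = idx[~s.mask[idx]]
        if idx.size == 0:
            raise ValueError("max_peak_band contains no valid points")
        offset = cfg.offset_fraction * float(np.max(s.values[idx]))
        in_offset = np.isin(seg_id, cfg.offset_segments)
        val = np.where(in_offset, val - offset, val)

    sw = np.sqrt(w)
    e0 = _rayleigh_prefit(lam, val, w)
    c0 = float(np.min(val))

    fixed_n = power_n is not None
    if variant == "fresnel_rayleigh":
        theta0 = np.array([1.33, 3000.0, 1.45, 3000.0, e0, c0])
        lower = np.array([1.0, 0.0, 1.0, 0.0, 0.0, -np.inf])
        upper = np.array([2.0, 1e5, 2.0, 1e5, np.inf, np.inf])
        names = ("a", "b", "c", "d", "e")
    elif variant == "rayleigh_only":
        theta0 = np.array([e0, c0])
        lower = np.array([0.0, -np.inf])
        upper = np.array([np.inf, np.inf])
        names = ("e",)
    else:  # power_law
        if fixed_n:
            if not 0 < power_n:
                raise ValueError("power_n must be > 0")
            # pre-fit e against λ^-n with n held fixed
            x = lam ** (-float(power_n))
            y = val - np.min(val)
            e0n = max(float(np.sum(w * x * y) / np.sum(w * x * x)), 0.0)
            theta0 = np.array([e0n, c0])
            lower = np.array([0.0, -np.inf])
            upper = np.array([np.inf, np.inf])
        else:
            theta0 = np.array([e0, 4.0, c0])
            lower = np.array([0.0, 1.0, -np.inf])
            upper = np.array([np.inf, 8.0, np.inf])
        names = ("e", "n")

    def expand(theta: np.ndarray) -> np.ndarray:
        """Reinsert a user-fixed power-law exponent into the vector."""
        if variant == "power_law" and fixed_n:
            return np.array([theta[0], float(power_n), theta[1]])
        return theta

    def residuals(theta):
        return sw * (_model(variant, expand(theta), lam) - val)

    rng = np.random.default_rng(0)
    best = None
    theta_try = theta0.copy()
    for attempt in range(max_restarts + 1):
        try:
            res = least_squares(residuals, np.clip(theta_try, lower, upper),
                                bounds=(lower, upper), method="trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                max_nfev=20000)
        except ValueError:
            res = None
        if res is not None and (best is None or res.cost < best.cost):
            best = res
        if best is not None and best.cost <= 1e-20 * max(1.0, np.sum((sw * val) ** 2)):
            break
        jitter = rng.uniform(0.8, 1.2, size=theta0.size)
        theta_try = theta0 * jitter

    if best is None or not np.all(np.isfinite(best.x)):
        raise FitConvergenceError(
            "baseline fit did not converge",
            diagnostics={"variant": variant,
                         "best_cost": None if best is None else float(best.cost)})

    theta = expand(best.x)
    params = dict(zip(names, theta[: len(names)]))
    const = float(theta[-1])

    fitted = _model(variant, theta, lam)
    seg_rms = []
    for k in range(len(cfg.segments)):
        m = seg_id == k
        seg_rms.append(float(np.sqrt(np.mean((fitted[m] - val[m]) ** 2))))

    diagnostics = {
        "segment_wavelengths": lam, "segment_values": val,
        "segment_id": seg_id, "fitted_at_segments": fitted,
        "grid": s.wavelengths,
        "fitted_on_grid": _model(variant, theta, s.wavelengths),
        "offset_subtracted": offset, "cost": float(best.cost),
        "n_restarts_used": 0, "warnings": [],
    }
    if variant == "power_law" and not fixed_n:
        n_fit = params["n"]
        if abs(n_fit - 1.0) < 1e-6 or abs(n_fit - 8.0) < 1e-6:
            diagnostics["warnings"].append(
                f"power-law exponent n = {n_fit:g} hit a bound of [1, 8]")
    fit = BaselineFit(variant=variant, params=params, const=const,
                      segment_rms=seg_rms, diagnostics=diagnostics)
    return fit


def subtract_baseline(s: Spectrum, fit: BaselineFit) -> Spectrum:
    """Subtract a fitted baseline, bringing the non-absorbing regions to 0.

    Masked points stay masked; the fit variant and parameters are logged
    in the spectrum history.
    """
    corrected = s.values - fit.evaluate(s.wavelengths)
    return s.with_values(
        corrected, op="subtract_baseline", variant=fit.variant,
        params={k: float(v) for k, v in fit.params.items()},
        const=fit.const)
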