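"""Band time traces and kinetic model fitting.

Once a spectral series is corrected, the absorbance inside a band that
is specific to one species — e.g. the 400 nm band of the blue-shifted M
intermediate of bacteriorhodopsin — is reduced to a single number per
time point, giving a time trace.  Three models are fitted by nonlinear
least squares:

mono-exponential (decay or rise, distinguished by the sign of y0 − y∞)::

    y(t) = y_inf + (y0 - y_inf) * exp(-k * t)

Hill (sigmoidal in log-time; amplitude may be negative, so the same form
fits rises and decays)::

    y(t) = base + amplitude * t^n / (t^n + K^n)

and a straight line for drift components.  The rate constant k (or the
half-transition time K) estimates the lifetime of an intermediate state;
amplitudes are reported as relative absorbance only — crystal optics
make absolute occupancies unreliable.

For irreversible reactions measured one-spectrum-per-crystal (serial
mode) the members must first be brought onto a common scale with
:func:`scale_series_pairwise`, and band *areas* rather than band means
are the robust observable (``mode="integral"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .core import FitConvergenceError, SpectrumSeries

__all__ = [
    "TimeTrace",
    "KineticFit",
    "extract_time_trace",
    "fit_kinetic",
    "scale_series_pairwise",
]

MODELS = ("exp_decay", "exp_rise", "hill", "linear")


@dataclass
class TimeTrace:
    """Band absorbance (mean or integral) versus time or dose."""

    times: np.ndarray
    values: np.ndarray
    band: tuple[float, float]
    mode: str = "mean"
    source: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(~np.isfinite(v)):
            raise ValueError("trace values must be finite")
        self.times, self.values = t, v

    def __len__(self) -> int:
        return self.times.size


@dataclass
class KineticFit:
    """Converged kinetic model with 1σ parameter uncertainties."""

    model: str
    params: dict[str, float]
    uncertainties: dict[str, float]
    fit_range: tuple[float, float]
    residual_rms: float
    diagnostics: dict = field(default_factory=dict)

    def evaluate(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.model in ("exp_decay", "exp_rise"):
            return p["y_inf"] + (p["y0"] - p["y_inf"]) * np.exp(-p["k"] * t)
        if self.model == "hill":
            return _hill(t, p["base"], p["amplitude"], p["K"], p["n"])
        if self.model == "linear":
            return p["intercept"] + p["slope"] * t
        raise ValueError(f"unknown model {self.model!r}")


def extract_time_trace(series: SpectrumSeries, band: tuple[float, float],
                       mode: str = "mean") -> TimeTrace:
    """Reduce each member to one number over a wavelength band.

    ``mean`` skips masked points inside the band; ``integral`` is the
    trapezoidal area in OD·nm with masked points linearly interpolated
    first (so adjacent-band integrals stay additive).
    """
    if mode not in ("mean", "integral"):
        raise ValueError("mode must be 'mean' or 'integral'")
    grid = series.wavelengths
    lo, hi = min(band), max(band)
    idx = np.nonzero((grid >= lo) & (grid <= hi))[0]
    if idx.size == 0:
        raise ValueError(f"band {band} does not intersect the grid")
    values = []
    for j, m in enumerate(series):
        if mode == "mean":
            keep = idx[~m.mask[idx]]
            if keep.size == 0:
                raise ValueError(
                    f"band {band} fully masked in member {j} "
                    f"(label {m.label!r})")
            values.append(float(np.mean(m.values[keep])))
        else:
            good = ~m.mask
            if not good[idx].any():
                raise ValueError(
                    f"band {band} fully masked in member {j} "
                    f"(label {m.label!r})")
            v = m.values
            if m.mask.any():
                v = np.interp(grid, grid[good], m.values[good])
            values.append(float(np.trapezoid(v[idx], grid[idx])))
    labels = series.labels
    times = labels if np.all(np.isfinite(labels)) else np.arange(len(series), dtype=float)
    return TimeTrace(times=times, values=np.asarray(values),
                     band=(lo, hi), mode=mode)


def _exp_model(t, y0, y_inf, k):
    return y_inf + (y0 - y_inf) * np.exp(-k * t)


def _hill(t, base, amplitude, K, n):
    t = np.asarray(t, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tn = np.power(np.maximum(t, 0.0), n)
        return base + amplitude * tn / (tn + K**n)


def _initial_exp(t, y):
    y0, y_inf = y[0], y[-1]
    # time where the trace first crosses halfway between start and end
    half = 0.5 * (y0 + y_inf)
    sign = np.sign(y0 - y_inf) or 1.0
    crossed = np.nonzero(sign * (y - half) <= 0)[0]
    t_mid = t[crossed[0]] if crossed.size else t[len(t) // 2]
    k0 = 1.0 / t_mid if t_mid > 0 else 1.0 / np.median(t[t > 0])
    return y0, y_inf, k0


def _initial_hill(t, y):
    base = y[0]
    amplitude = y[-1] - y[0]
    half = base + 0.5 * amplitude
    sign = np.sign(amplitude) or 1.0
    crossed = np.nonzero(sign * (y - half) >= 0)[0]
    K0 = t[crossed[0]] if crossed.size else np.median(t[t > 0])
    if K0 <= 0:
        K0 = np.median(t[t > 0])
    return base, amplitude, K0, 1.0


def fit_kinetic(trace: TimeTrace, model: str,
                fit_range: tuple[float, float] | None = None,
                weights: np.ndarray | None = None) -> KineticFit:
    """Fit a kinetic model to a time trace by nonlinear least squares.

    ``fit_range`` restricts the fitted points to a closed time interval
    (e.g. the rise phase only).  ``weights`` are optional 1/σ² weights of
    the same length as the full trace.  Raises
    :class:`FitConvergenceError` with best-so-far diagnostics when the
    optimizer fails.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    t, y = trace.times, trace.values
    sel = np.ones(t.size, dtype=bool)
    if fit_range is not None:
        lo, hi = min(fit_range), max(fit_range)
        sel = (t >= lo) & (t <= hi)
    t, y = t[sel], y[sel]
    sigma = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)[sel]
        sigma = 1.0 / np.sqrt(w)
    min_pts = {"exp_decay": 4, "exp_rise": 4, "hill": 5, "linear": 2}[model]
    if t.size < min_pts:
        raise ValueError(f"{model} needs >= {min_pts} points in fit_range, "
                         f"got {t.size}")
    fr = (float(t[0]), float(t[-1]))

    if model == "linear":
        # closed-form weighted straight line
        W = np.ones_like(t) if sigma is None else 1.0 / sigma**2
        A = np.vstack([np.ones_like(t), t]).T
        coef, *_ = np.linalg.lstsq(A * W[:, None], y * W, rcond=None)
        resid = y - (coef[0] + coef[1] * t)
        dof = max(t.size - 2, 1)
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(A.T @ (A * W[:, None]))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
        return KineticFit(
            model="linear",
            params={"intercept": float(coef[0]), "slope": float(coef[1])},
            uncertainties={"intercept": float(np.sqrt(cov[0, 0])),
                           "slope": float(np.sqrt(cov[1, 1]))},
            fit_range=fr,
            residual_rms=float(np.sqrt(np.mean(resid**2))),
            diagnostics={"r_squared": r2})

    if model in ("exp_decay", "exp_rise"):
        p0 = _initial_exp(t, y)
        names = ("y0", "y_inf", "k")
        fn = _exp_model
        bounds = ([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf])
    else:
        p0 = _initial_hill(t, y)
        names = ("base", "amplitude", "K", "n")
        fn = _hill
        bounds = ([-np.inf, -np.inf, 1e-300, 1e-6],
                  [np.inf, np.inf, np.inf, np.inf])

    try:
        popt, pcov = curve_fit(fn, t, y, p0=p0, sigma=sigma, bounds=bounds,
                               maxfev=20000, xtol=1e-14, ftol=1e-14)
    except RuntimeError as exc:
        raise FitConvergenceError(
            f"{model} fit did not converge: {exc}",
            diagnostics={"p0": list(p0), "n_points": int(t.size)}) from exc

    resid = y - fn(t, *popt)
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else \
        np.full(len(popt), np.nan)
    params = dict(zip(names, map(float, popt)))
    if model in ("exp_decay", "exp_rise") and params["k"] <= 0:
        raise FitConvergenceError("fitted rate constant is non-positive",
                                  diagnostics={"params": params})
    return KineticFit(model=model, params=params,
                      uncertainties=dict(zip(names, map(float, perr))),
                      fit_range=fr,
                      residual_rms=float(np.sqrt(np.mean(resid**2))),
                      diagnostics={"n_points": int(t.size)})


def scale_series_pairwise(series: SpectrumSeries,
                          conserved_band: tuple[float, float]
                          ) -> SpectrumSeries:
    """Equalize per-crystal thickness by scaling to a conserved band.

    Each member is multiplied so its maximum inside ``conserved_band``
    equals the series *median* of those maxima; the factors are recorded
    in each member's history.  Used in serial mode, where every spectrum
    comes from a different crystal.
    """
    grid = series.wavelengths
    lo, hi = min(conserved_band), max(conserved_band)
    idx = np.nonzero((grid >= lo) & (grid <= hi))[0]
    if idx.size == 0:
        raise ValueError(f"band {conserved_band} does not intersect the grid")
    maxima = []
    for j, m in enumerate(series):
        keep = idx[~m.mask[idx]]
        if keep.size == 0:
            raise ValueError(f"band fully masked in member {j}")
        mx = float(np.max(m.values[keep]))
        if mx <= 0:
            raise ValueError(
                f"member {j} has non-positive band maximum {mx:g}")
        maxima.append(mx)
    target = float(np.median(maxima))
    members = [
        m.with_values(m.values * (target / mx), op="scale_series_pairwise",
                      factor=target / mx,
                      band=[lo, hi])
        for m, mx in zip(series, maxima)
    ]
    return SpectrumSeries(members, axis=series.axis)
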