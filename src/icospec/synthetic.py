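"""Synthetic single-crystal spectra with realistic optical artefacts.

Every correction in this package assumes a specific optical structure:
Gaussian absorption bands riding on a reflectivity + Rayleigh baseline,
detector noise, fluorescence dips, saturation plateaus, nanosecond-laser
dents and exponential/Hill time evolution.  This module generates raw
detector traces and kinetic series with exactly that structure, from a
declarative :class:`SimSpec`, so every other module can be exercised —
and its accuracy measured against known ground truth — without any
instrument data.

The forward model inverts the absorbance equation: given the true
absorbance A(λ), the sample trace is

    I_sample = I_background + (I_reference - I_background) · 10^(-A(λ))

with the reference modelled as a smooth lamp envelope (two broad
Gaussians reaching 80% of detector full scale), dark counts as a small
constant, saturation as clamping at full scale, and noise (multiplicative
Gaussian on counts plus additive detector noise) applied last.  All
randomness flows from the spec's seed, so a fixed spec reproduces its
output bit for bit.

Two ready-made scenarios mirror canonical photochemistry:

``br_series``    a bacteriorhodopsin-like photocycle — ground-state band
                 at 600 nm dropping and recovering, M-state band at
                 400 nm rising then decaying, 12 log-spaced delays from
                 3 µs to 1 s, optional decaying laser dent at 560 nm.
``lov2_series``  a LOV2-like photoadduct relaxation — difference spectra
                 with a negative 390 nm band and a positive 420–500 nm
                 band decaying mono-exponentially, plus a small linear
                 drift component.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import RawTrace, Spectrum, SpectrumSeries

__all__ = ["SimSpec", "simulate_traces", "simulate_series", "br_series",
           "br_raw_traces", "lov2_series", "default_grid", "BR_TIMES",
           "true_absorbance", "amplitude_law"]

# canonical 12-point log-spaced delay grid, 3 µs .. 1 s
BR_TIMES = (3e-6, 1e-5, 3e-5, 1e-4, 3e-4, 1e-3,
            3e-3, 1e-2, 3e-2, 1e-1, 3e-1, 1.0)


def default_grid(lo: float = 300.0, hi: float = 800.0,
                 step: float = 0.5) -> np.ndarray:
    return np.arange(lo, hi + step / 2, step)


@dataclass
class SimSpec:
    """Declarative description of a synthetic measurement.

    peaks : list of (centre nm, sigma nm, amplitude OD)
    baseline : {"variant": ..., "params": {...}, "const": ...} or None
    noise_multiplicative : fractional Gaussian sigma on counts
    noise_additive : additive Gaussian sigma, counts
    fluorescence_dip : (centre, sigma, depth OD) or None
    laser_dent : (centre nm, sigma nm, depth OD, per-member decay rate 1/s)
        or None — the dent amplitude decays exponentially along the series.
    saturation_band : (lo, hi) nm where the *lamp* is boosted above full
        scale, producing a clamped plateau, or None.
    kinetics : one amplitude law per peak (see :func:`amplitude_law`) or None.
    drift : (sigma nm, centre nm, OD per unit label) linear-in-time
        spectral drift added to series members, or None.
    times : series labels, seconds (or dose).
    """

    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    baseline: dict | None = None
    noise_multiplicative: float = 0.0
    noise_additive: float = 0.0
    fluorescence_dip: tuple[float, float, float] | None = None
    laser_dent: tuple[float, float, float, float] | None = None
    saturation_band: tuple[float, float] | None = None
    kinetics: list[dict] | None = None
    drift: tuple[float, float, float] | None = None
    times: tuple[float, ...] = ()
    grid: np.ndarray = field(default_factory=default_grid)
    detector_full_scale: float = 65535.0
    background_level: float = 400.0
    seed: int = 0

    def __post_init__(self):
        for c, s, a in self.peaks:
            if s <= 0:
                raise ValueError("peak sigma must be > 0")
            if a < 0:
                raise ValueError("peak amplitude must be >= 0")
        self.grid = np.asarray(self.grid, dtype=float)


def _gauss(lam: np.ndarray, centre: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - centre) / sigma) ** 2)


def _baseline_curve(spec: SimSpec) -> np.ndarray:
    lam = spec.grid
    if spec.baseline is None:
        return np.zeros_like(lam)
    variant = spec.baseline.get("variant", "rayleigh_only")
    p = spec.baseline.get("params", {})
    const = spec.baseline.get("const", 0.0)
    if variant == "fresnel_rayleigh":
        n1 = p["a"] + p["b"] / lam**2
        n2 = p["c"] + p["d"] / lam**2
        return ((n1 - n2) / (n1 + n2)) ** 2 + p["e"] / lam**4 + const
    if variant == "rayleigh_only":
        return p["e"] / lam**4 + const
    if variant == "power_law":
        return p["e"] * lam ** (-p["n"]) + const
    raise ValueError(f"unknown baseline variant {variant!r}")


def amplitude_law(law: dict | None, t: float) -> float:
    """Evaluate a kinetic amplitude law at time ``t`` (result in [0, ...])."""
    if law is None:
        return 1.0
    kind = law["kind"]
    if kind == "constant":
        return float(law.get("value", 1.0))
    if kind == "exp_decay":
        return float(np.exp(-law["k"] * t))
    if kind == "exp_rise":
        return float(1.0 - np.exp(-law["k"] * t))
    if kind == "hill":
        K, n = law["K"], law.get("n", 1.0)
        return float(t**n / (t**n + K**n)) if t > 0 else 0.0
    if kind == "linear":
        return float(law.get("offset", 0.0) + law["slope"] * t)
    if kind == "rise_fall":
        # sequential intermediate: populated at k_rise, drained at k_fall
        return float((1.0 - np.exp(-law["k_rise"] * t)) *
                     np.exp(-law["k_fall"] * t))
    if kind == "ground_depletion":
        # ground state mirrors an intermediate's occupancy
        occ = (1.0 - np.exp(-law["k_rise"] * t)) * np.exp(-law["k_fall"] * t)
        return float(1.0 - law.get("depth", 1.0) * occ)
    raise ValueError(f"unknown kinetic law {kind!r}")


def true_absorbance(spec: SimSpec, t: float | None = None) -> np.ndarray:
    """Ground-truth absorbance on the grid, at time ``t`` if kinetic."""
    lam = spec.grid
    a = _baseline_curve(spec)
    laws = spec.kinetics or [None] * len(spec.peaks)
    if len(laws) != len(spec.peaks):
        raise ValueError("one kinetic law per peak required")
    for (centre, sigma, amp), law in zip(spec.peaks, laws):
        scale = amplitude_law(law, t) if t is not None else 1.0
        a = a + amp * scale * _gauss(lam, centre, sigma)
    if spec.fluorescence_dip is not None:
        c, s, depth = spec.fluorescence_dip
        a = a - depth * _gauss(lam, c, s)
    return a


def _lamp_envelope(spec: SimSpec) -> np.ndarray:
    """Smooth polychromatic lamp: two broad Gaussians, peak 80% full scale."""
    lam = spec.grid
    shape = (_gauss(lam, 480.0, 110.0) + 0.55 * _gauss(lam, 650.0, 160.0))
    env = shape / shape.max() * 0.8 * spec.detector_full_scale
    if spec.saturation_band is not None:
        lo, hi = spec.saturation_band
        boost = (lam >= lo) & (lam <= hi)
        env = np.where(boost, 1.4 * spec.detector_full_scale, env)
    return env


def simulate_traces(spec: SimSpec, t: float | None = None,
                    rng: np.random.Generator | None = None
                    ) -> tuple[RawTrace, RawTrace, RawTrace]:
    """Generate (sample, reference, background) raw traces.

    Saturation clamps counts at detector full scale; noise is applied
    last.  With the default zero-noise spec the forward model is exactly
    inverted by absorbance computation wherever nothing clamps.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    lam = spec.grid
    bg = np.full_like(lam, spec.background_level)
    ref = bg + _lamp_envelope(spec)
    a_true = true_absorbance(spec, t)
    if t is not None and spec.laser_dent is not None:
        c, s, depth, decay = spec.laser_dent
        a_true = a_true - depth * np.exp(-decay * t) * _gauss(lam, c, s)
    sample = bg + (ref - bg) * np.power(10.0, -a_true)

    def finish(counts: np.ndarray, role: str) -> RawTrace:
        out = counts.copy()
        if spec.noise_multiplicative > 0:
            out = out * (1.0 + spec.noise_multiplicative *
                         rng.standard_normal(out.size))
        if spec.noise_additive > 0:
            out = out + spec.noise_additive * rng.standard_normal(out.size)
        out = np.clip(out, 0.0, spec.detector_full_scale)
        return RawTrace(lam, out, role=role,
                        detector_full_scale=spec.detector_full_scale,
                        source_id=f"synthetic seed={spec.seed}")

    return finish(sample, "sample"), finish(ref, "reference"), finish(bg, "background")


def simulate_series(spec: SimSpec, as_absorbance: bool = True
                    ) -> SpectrumSeries:
    """Generate a kinetic series of absorbance spectra.

    Peak amplitudes follow the per-peak laws in ``spec.kinetics``; the
    optional laser dent decays along the series and the optional drift
    spectrum grows linearly with the label.  Noise here is additive
    Gaussian OD with sigma ``noise_multiplicative`` × the largest peak
    amplitude (absorbance-domain noise; use :func:`simulate_traces` per
    time point for count-domain noise).
    """
    if not spec.times:
        raise ValueError("spec.times must be non-empty")
    rng = np.random.default_rng(spec.seed)
    lam = spec.grid
    peak_amp = max((a for _, _, a in spec.peaks), default=1.0)
    members = []
    for t in spec.times:
        a = true_absorbance(spec, t)
        if spec.laser_dent is not None:
            c, s, depth, decay = spec.laser_dent
            a = a - depth * np.exp(-decay * t) * _gauss(lam, c, s)
        if spec.drift is not None:
            sig, centre, rate = spec.drift
            a = a + rate * t * _gauss(lam, centre, sig)
        if spec.noise_multiplicative > 0:
            a = a + (spec.noise_multiplicative * peak_amp *
                     rng.standard_normal(lam.size))
        members.append(Spectrum(lam, a, kind="absorbance", label=float(t),
                                history=[{"op": "simulate", "t": float(t),
                                          "seed": spec.seed}]))
    members.sort(key=lambda m: m.label)
    return SpectrumSeries(members, axis="time")


def br_series(seed: int = 0, noise: float = 0.0,
              dent_depth: float = 0.5, k_rise: float = 4e4,
              k_fall: float = 60.0, times: tuple[float, ...] = BR_TIMES
              ) -> tuple[SimSpec, SpectrumSeries]:
    """Bacteriorhodopsin-like photocycle series (M state rise and decay).

    Ground-state band at 600 nm is depleted while the M state is
    populated (mirror of the 400 nm law); the 400 nm M band rises with
    ``k_rise`` and decays with ``k_fall``, so its maximum falls near
    ln(k_rise/k_fall)/(k_rise − k_fall).  A laser dent at 560 nm decays
    along the series.
    """
    spec = SimSpec(
        peaks=[(600.0, 40.0, 0.8), (400.0, 25.0, 0.5), (280.0, 25.0, 1.0)],
        kinetics=[
            # ground state depleted while the M intermediate is occupied
            {"kind": "ground_depletion", "k_rise": k_rise, "k_fall": k_fall,
             "depth": 0.6},
            {"kind": "rise_fall", "k_rise": k_rise, "k_fall": k_fall},
            {"kind": "constant", "value": 1.0},
        ],
        baseline={"variant": "rayleigh_only", "params": {"e": 2e9},
                  "const": 0.1},
        laser_dent=(560.0, 3.0, dent_depth, 8.0),
        noise_multiplicative=noise,
        times=tuple(times),
        seed=seed,
    )
    return spec, simulate_series(spec)


def br_raw_traces(seed: int = 0, noise: float = 0.0,
                  times: tuple[float, ...] = BR_TIMES
                  ) -> list[tuple[float, RawTrace, RawTrace, RawTrace]]:
    """Per-delay raw detector traces for the bacteriorhodopsin scenario.

    One (t, sample, reference, background) triple per delay, each with an
    independent noise stream derived from ``seed``; feed these through
    absorbance computation to start the pipeline from counts.
    """
    spec, _ = br_series(seed=seed, noise=0.0, times=times)
    spec = replace(spec, noise_multiplicative=noise)
    out = []
    for i, t in enumerate(times):
        rng = np.random.default_rng((seed, i))
        sample, ref, bg = simulate_traces(spec, t=t, rng=rng)
        out.append((t, sample, ref, bg))
    return out


def lov2_series(seed: int = 0, k: float = 2.0e-3, noise: float = 0.0015,
                drift_rate: float = -2.0e-6,
                times: tuple[float, ...] | None = None
                ) -> tuple[SimSpec, SpectrumSeries]:
    """LOV2-like photoadduct relaxation as *difference* spectra.

    Members are light − dark differences: a negative band at 390 nm
    (photoadduct depletion) and a larger positive band spanning
    420–500 nm (ground-state recovery), both decaying mono-exponentially
    with rate ``k`` (s⁻¹; the default τ = 500 s relaxation is fully
    sampled within the ~67 min collection), plus a small spectrally
    smooth component drifting linearly in time (crystal displacement in
    the loop, ~8 mOD over the collection).
    """
    if times is None:
        times = tuple(np.linspace(0.0, 4000.0, 40))
    lam = default_grid(330.0, 650.0, 0.5)
    rng = np.random.default_rng(seed)
    shape = (-0.7 * _gauss(lam, 390.0, 14.0)
             + 0.65 * _gauss(lam, 447.0, 26.0)
             + 0.50 * _gauss(lam, 475.0, 22.0))
    drift_shape = _gauss(lam, 520.0, 120.0)
    members = []
    for t in times:
        a = 0.30 * np.exp(-k * t) * shape + drift_rate * t * drift_shape
        if noise > 0:
            a = a + noise * rng.standard_normal(lam.size)
        members.append(Spectrum(lam, a, kind="absorbance", label=float(t),
                                history=[{"op": "simulate_lov2",
                                          "t": float(t), "seed": seed}]))
    spec = SimSpec(peaks=[(390.0, 14.0, 0.30)], times=tuple(times),
                   grid=lam, seed=seed,
                   drift=(120.0, 520.0, drift_rate))
    return spec, SpectrumSeries(members, axis="time")
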