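# Methods

This note records the models implemented in `icospec`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that matter when reading results.

## Absorbance and confidence

Absorbance is computed point-wise from the three detector traces,
`A = −log10[(I_sample − I_bg)/(I_ref − I_bg)]`. Points where either net
count is ≤ 0 have no physical transmission value; they are **masked**,
never clamped, so the wavelength grid survives into series operations
and SVD. Masks propagate by union through differences and are written to
ASCII as `nan` sentinels so files round-trip.

The per-wavelength confidence score is a deliberately simple monotone
heuristic (the concept comes from beamline practice; no standard formula
exists): per trace, `s(I) = clip((I − I_bg − low)/ramp, 0, 1)`, zeroed on
saturation plateaus, combined across sample and reference by pointwise
minimum. Defaults are expressed as fractions of detector full scale —
`low` = 2%, `ramp` = 8%, saturation tolerance 0.5%, plateau run length
3 — conservative values for 16-bit-class CCDs; all are per-call
parameters. Saturation of *either* trace zeroes the score: a clipped
reference distorts absorbance exactly as a clipped sample does.

## Baseline models

The full model is

    B(λ) = ((n1 − n2)/(n1 + n2))² + e/λ⁴ + const,  n_i(λ) = a_i + b_i/λ²

i.e. normal-incidence Fresnel reflectivity of **one effective
crystal/liquor interface** between two Cauchy media, plus Rayleigh
scattering and a flat focal-loss term. A real mounted crystal has
several interfaces; their reflectivities are small (R ≪ 1) and additive
to first order, so a single effective interface with data-driven Cauchy
coefficients absorbs them. The reflectivity is fitted in OD directly
rather than as −log10(1 − R): for R ≪ 1 the two differ by a
near-constant factor that the free parameters absorb.

**Identifiability.** Only the contrast (n1 − n2)/(n1 + n2) enters the
model, so the individual coefficients a, b versus c, d are structurally
degenerate: many parameter vectors produce the same curve. The fitted
*curve* is well determined (recovered within half a percent of the main
peak amplitude on noiseless synthetic truth); the parameter vector is
reported but should not be interpreted as material constants. For the
`rayleigh_only` and `power_law` variants the parameters are identifiable
and recovered exactly on noiseless input.

Fitting is weighted nonlinear least squares (scipy `least_squares`, TRF)
over the union of 1–3 user segments, per-point weight 1/divergence of
the owning segment, with no per-segment length normalization — the
divergence factor is the user's instrument-knowledge knob and the
documented convention is to set it inversely proportional to segment
length. Initialization: a = 1.33 (water-like), c = 1.45 (protein-like),
b = d = 3000 nm², `e` from a closed-form one-parameter λ⁻⁴ pre-fit,
const = segment minimum; bounds a, c ∈ [1, 2], b, d ∈ [0, 10⁵] nm²,
e ≥ 0; up to 5 restarts jitter the start ±20% (deterministically
seeded). The optional offset — a fraction of the maximum absorbance in a
user-named peak band — is subtracted from the observed values of the
designated segments before fitting, which forces the fitted curve to run
below those points without changing the model. The power-law exponent is
fitted within [1, 8] unless fixed; hitting a bound leaves a warning in
the diagnostics. Segment intervals are closed: boundary wavelengths
belong to the segment.

## Smoothing

Savitzky–Golay with degree 3 over 21-point windows is the default
(≈10 nm at 0.5 nm sampling — wide enough to suppress shot noise, narrow
enough to preserve protein absorption bands of σ ≳ 10 nm). Edges are
handled by fitting the first/last full window and evaluating the
polynomial off-centre (scipy's `interp` mode). Mirror padding was
considered and rejected: reflection is not polynomial-preserving, so it
would break the filter's defining property that polynomials up to the
fit degree pass through unchanged. The rolling mean keeps mirror-padded
edges (it only needs to preserve constants). With masks present, each
output point is re-fitted on the unmasked points of its
boundary-clamped window when at least degree + 2 survive; otherwise the
point is masked.

## Laser-dent removal

Dips are candidate local minima of the smoothed spectrum with prominence
above a threshold (default 5× the robust noise σ, estimated from the
median absolute successive difference of the detrended spectrum). The
dip's extent comes from the Savitzky–Golay second derivative: a dip has
a positive-curvature core flanked by negative lobes whose minima mark
its inflection shoulders (±√3 σ for a Gaussian). The boundary is where
the lobe curvature has faded below 2% of the central curvature or flips
sign, capped at 1.8× the shoulder distance (≈3σ) so the walk cannot
bleed into a neighbouring absorption band. The inner zero-crossings
alone (at ±σ) were rejected: a Gaussian dip is still ~60% deep there,
and interpolating across so narrow an interval leaves most of the
artefact in place. The deepest dip (depth measured from the straight
line joining its boundaries) is the laser contribution; ties break
toward shorter wavelength; all other dips are catalogued as minor.
Note that a valley between two absorption bands is a genuine local
minimum and is listed among the dips — in a series the amplitude
criterion keeps it from being mistaken for the laser.

Within a series the pump wavelength is fixed, so members after the first
are searched only inside the first dent's interval widened by one
smoothing window; a member with no detectable dip there still has the
template interval removed, because the laser fires on every exposure.
Removal masks the points (grid-preserving) or linearly interpolates
across the interval.

## Kinetics

Band traces are the mean of unmasked band values (mode `mean`) or the
trapezoidal integral with masked points interpolated first (mode
`integral`, OD·nm) — interpolation keeps integrals additive over
adjacent bands. Models: mono-exponential (rise and decay are the same
form; the sign of y₀ − y∞ distinguishes them) and Hill with time as the
dose variable and free-signed amplitude. Initial guesses are derived
from the trace (endpoints for the levels, the half-crossing time for k
or K, n = 1) and recover noiseless parameters to ≤ 0.01%. Uncertainties
are 1σ from the converged covariance; fits are unweighted by default
with optional 1/σ² weights. Serial-mode series (one crystal per
spectrum) are first scaled so each member's conserved-band maximum
equals the series median — the median is robust to a few outlier
crystals. Occupancies are reported only as relative amplitudes.

## SVD

The difference-spectra matrix (time × wavelength, chronological rows) is
decomposed by thin SVD without mean-centering — difference spectra are
already centred on the dark state; a `center` flag exists. Masked points
are interpolated per row, or their wavelength columns dropped
consistently across all rows. Sign convention: each basis spectrum is
flipped so its largest-|value| element is positive, with the time course
flipped along, keeping the reconstruction exact. Component selection is
left to the user; explained variance S_i²/ΣS² is reported. Component
time courses can be handed directly to the kinetic fitter; a linear
model is provided for drift components.

One structural caveat, visible in the synthetic LOV2 scenario: SVD time
courses are orthogonal by construction, so when two physical processes
have *correlated* time courses (an exponential that has not finished
decaying looks much like a ramp) the components are rotations of the
physical ones and the secondary time course is nonlinear even without
noise. The scenario therefore samples the relaxation well past
completion (40 spectra over 4000 s for τ = 500 s), which is also how
such an experiment should be designed.

## The synthetic generator

`simulate_traces` inverts the absorbance equation: true absorbance
(Gaussian bands + baseline + artefact dips) → transmitted counts under a
smooth two-Gaussian lamp envelope peaking at 80% of a 65535-count full
scale, dark counts at 400, saturation as clamping, then multiplicative
and additive Gaussian noise. All randomness flows from the spec's seed;
identical specs are bit-identical. The forward-inverse identity
(absorbance of simulated traces equals the true absorbance to 1e-10
wherever nothing clamps) is asserted in the tests.

Scenario defaults: the bacteriorhodopsin-like series uses a 0.8 OD
ground band at 600 nm, a 0.5 OD M band at 400 nm with occupancy
(1 − e^(−k_rise t))·e^(−k_fall t), k_rise = 4×10⁴ s⁻¹,
k_fall = 60 s⁻¹, the canonical 12 log-spaced delays 3 µs–1 s, and a
0.5 OD laser dent at the 560 nm pump wavelength (σ = 3 nm) decaying at
8 s⁻¹ along the series. The LOV2-like series holds difference spectra: a
−0.21 OD photoadduct band at 390 nm and a larger positive 420–500 nm
ground-state band decaying at k = 2×10⁻³ s⁻¹, 1.5 mOD white noise, and a
−2×10⁻⁶ OD/s drift on a broad 520 nm shape (≈8 mOD over the
collection, the scale of crystal-slippage drifts at room temperature).

What the generator does **not** emulate: anisotropic/polarization
effects, fluorescence self-absorption, wavelength-correlated (pink)
noise, lamp flicker between exposures, and non-Gaussian band shapes.
Passing tests therefore demonstrate correctness of the corrections under
the stated optical model, not robustness to every instrument pathology;
the confidence score and diagnostic outputs exist precisely because real
data will deviate.

## Numerical conventions

- Wavelength grids are strictly increasing; duplicate wavelengths on
  read are an error (they indicate a corrupted export), reversed files
  are sorted.
- Series resampling is linear interpolation onto the first member's grid
  restricted to the common range, performed once at construction.
- Band intervals are closed on both ends.
- History is append-only and serialized into the ASCII headers; nothing
  timestamped enters an output file, so identical runs are
  byte-identical.
- Problem sizes used by the test-suite and the acceptance script (≈1000
  grid points, 12–40 series members, 100 Monte-Carlo replicates) were
  chosen as the smallest sizes at which the statistical checks are
  stable across seeds.
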