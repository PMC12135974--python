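"""Singular value decomposition of difference-spectra series.

A time-resolved series of light − dark difference spectra is arranged as
a matrix A (time × wavelength, chronological rows).  Its thin SVD
A = U·S·Vᵀ separates the data into a minimal set of time-invariant basis
spectra (columns of V, denoted lSV here as they live on the wavelength
axis), their weights (singular values) and their time courses (columns
of U, denoted rSV).  For a clean one-step reaction the first component
carries the whole photochemistry and its time course follows the
reaction kinetics; slow drifts (e.g. crystal displacement in the loop)
show up as additional quasi-linear components.

SVD signs are arbitrary, so each basis spectrum is flipped to make its
largest-magnitude element positive; time courses are flipped with them,
keeping the reconstruction exact.  No mean-centering is applied by
default — difference spectra already remove the static signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GridMismatchError, Spectrum, SpectrumSeries
from .kinetics import KineticFit, TimeTrace, fit_kinetic
from .preprocess import difference_series

__all__ = ["SVDResult", "build_difference_matrix", "svd_decompose",
           "component_kinetics"]


@dataclass
class SVDResult:
    """Thin SVD of a spectra matrix, with axis metadata."""

    lsv: np.ndarray              # wavelength × component basis spectra
    singular_values: np.ndarray  # non-increasing, >= 0
    rsv: np.ndarray              # time × component time courses
    explained_variance: np.ndarray
    wavelengths: np.ndarray
    labels: np.ndarray
    input_shape: tuple[int, int]
    meta: dict = field(default_factory=dict)

    @property
    def rank(self) -> int:
        tol = max(self.input_shape) * np.finfo(float).eps * (
            self.singular_values[0] if self.singular_values.size else 0.0)
        return int(np.sum(self.singular_values > tol))

    def reconstruct(self, n_components: int | None = None) -> np.ndarray:
        """A ≈ rSV · diag(S) · lSVᵀ truncated to ``n_components``."""
        k = self.singular_values.size if n_components is None else n_components
        return (self.rsv[:, :k] * self.singular_values[:k]) @ self.lsv[:, :k].T


def build_difference_matrix(series: SpectrumSeries,
                            dark: Spectrum | float | int | None = None,
                            mask_policy: str = "interpolate") -> tuple[np.ndarray, SpectrumSeries]:
    """Assemble the (time × wavelength) matrix of difference spectra.

    ``dark`` may be a Spectrum on the series grid, a member label (the
    matching member is used as the dark state), or None when the series
    already holds difference spectra.  Masked points are linearly
    interpolated (``mask_policy="interpolate"``) or their wavelength
    columns dropped consistently across all rows (``"drop"``).

    Returns the matrix and the (possibly differenced) series it came
    from; when columns were dropped the reduced grid is in
    ``series.wavelengths`` of the returned series.
    """
    if mask_policy not in ("interpolate", "drop"):
        raise ValueError("mask_policy must be 'interpolate' or 'drop'")
    if dark is None:
        diff = series
    elif isinstance(dark, Spectrum):
        diff = difference_series(series, dark)
    else:
        labels = series.labels
        hits = np.nonzero(np.isclose(labels, float(dark)))[0]
        if hits.size != 1:
            raise ValueError(f"label {dark!r} matches {hits.size} members")
        diff = difference_series(series, series[hits[0]])

    grid = diff.wavelengths
    rows = np.vstack([m.values for m in diff])
    masks = np.vstack([m.mask for m in diff])
    if masks.any():
        if mask_policy == "interpolate":
            for i, m in enumerate(diff):
                if m.mask.any():
                    good = ~m.mask
                    if not good.any():
                        raise ValueError(f"member {i} is fully masked")
                    rows[i] = np.interp(grid, grid[good], rows[i][good])
        else:
            drop = masks.any(axis=0)
            if drop.all():
                raise ValueError("every wavelength column carries a mask")
            rows = rows[:, ~drop]
            members = [Spectrum(grid[~drop], m.values[~drop], kind=m.kind,
                                label=m.label, history=m.history,
                                mask=m.mask[~drop]) for m in diff]
            diff = SpectrumSeries(members, axis=diff.axis)
    return rows, diff


def svd_decompose(A: np.ndarray, n_components: int | None = None,
                  wavelengths: np.ndarray | None = None,
                  labels: np.ndarray | None = None,
                  center: bool = False) -> SVDResult:
    """Thin SVD of a spectra matrix (rows = chronological spectra).

    Each basis spectrum is sign-flipped so its largest-|value| element is
    positive.  ``center=True`` removes the column means first (off by
    default: difference spectra are already centred on the dark state).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.size == 0:
        raise ValueError("A must be a non-empty 2-D matrix")
    work = A - A.mean(axis=0, keepdims=True) if center else A
    U, S, Vt = np.linalg.svd(work, full_matrices=False)
    V = Vt.T
    # sign convention: dominant element of each basis spectrum positive
    for j in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
            U[:, j] = -U[:, j]
    if n_components is not None:
        U, S, V = U[:, :n_components], S[:n_components], V[:, :n_components]
    total = float(np.sum(S**2))
    explained = S**2 / total if total > 0 else np.zeros_like(S)
    nt, nw = A.shape
    return SVDResult(
        lsv=V, singular_values=S, rsv=U, explained_variance=explained,
        wavelengths=(np.arange(nw, dtype=float) if wavelengths is None
                     else np.asarray(wavelengths, float)),
        labels=(np.arange(nt, dtype=float) if labels is None
                else np.asarray(labels, float)),
        input_shape=(nt, nw), meta={"centered": center})


def component_kinetics(result: SVDResult, component: int,
                       model: str = "exp_decay",
                       fit_range: tuple[float, float] | None = None,
                       weight_by_singular_value: bool = False) -> KineticFit:
    """Fit a kinetic model to one right-singular-vector time course.

    The rSV column is treated as a time trace over the series labels and
    handed to :func:`icospec.kinetics.fit_kinetic`; ``model="linear"``
    suits drift components.  With ``weight_by_singular_value`` the trace
    is scaled by its singular value so amplitudes are in data units.
    """
    if not 0 <= component < result.singular_values.size:
        raise ValueError(
            f"component {component} out of range "
            f"(have {result.singular_values.size})")
    y = result.rsv[:, component]
    if weight_by_singular_value:
        y = y * result.singular_values[component]
    trace = TimeTrace(times=result.labels, values=y,
                      band=(float(result.wavelengths[0]),
                            float(result.wavelengths[-1])),
                      mode="mean", source=f"rSV_{component}")
    return fit_kinetic(trace, model=model, fit_range=fit_range)
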