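"""Core containers for in crystallo optical spectroscopy data.

Three containers cover the whole workflow:

``RawTrace``
    one detector readout (counts versus wavelength) with a role —
    ``sample`` (light through the crystal), ``reference`` (lamp, no
    sample) or ``background`` (lamp off, dark counts).

``Spectrum``
    a wavelength-indexed absorbance (or fluorescence) curve carrying an
    append-only history of the corrections applied to it and an optional
    per-point mask for invalid values (non-positive transmission, removed
    laser-dent points, ...).

``SpectrumSeries``
    an ordered collection of spectra on one shared wavelength grid,
    labelled by time, dose or plain index.

Masks follow the :mod:`numpy.ma` convention: ``True`` marks an *invalid*
point.  Masked points are carried, never dropped, so that every member of
a series keeps an identical grid (a requirement for difference spectra
and SVD).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Iterator, Sequence

import numpy as np

__all__ = [
    "RawTrace",
    "Spectrum",
    "SpectrumSeries",
    "SpectrumFormatError",
    "GridMismatchError",
    "FitConvergenceError",
]

ROLES = ("sample", "reference", "background")
KINDS = ("absorbance", "fluorescence")
AXES = ("time", "dose", "index")


class SpectrumFormatError(ValueError):
    """A file or array does not form a valid spectrum."""


class GridMismatchError(ValueError):
    """Two objects that must share a wavelength grid do not."""


class FitConvergenceError(RuntimeError):
    """A nonlinear fit failed to converge; carries best-so-far diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def _as_grid(wavelengths: Sequence[float]) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size < 2:
        raise SpectrumFormatError("need a 1-D wavelength grid with >= 2 points")
    dw = np.diff(wl)
    if np.any(dw <= 0):
        bad = wl[1:][dw <= 0][0]
        raise SpectrumFormatError(
            f"wavelengths must be strictly increasing (offender near {bad:g} nm)"
        )
    return wl


@dataclass(frozen=True)
class RawTrace:
    """One spectrometer readout: counts on a strictly increasing grid."""

    wavelengths: np.ndarray
    counts: np.ndarray
    role: str
    integration_time: float | None = None
    detector_full_scale: float | None = None
    source_id: str = ""

    def __post_init__(self):
        wl = _as_grid(self.wavelengths)
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != wl.shape:
            raise SpectrumFormatError("counts and wavelengths differ in length")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return self.wavelengths.size

    def resample(self, grid: np.ndarray) -> "RawTrace":
        """Linear interpolation onto ``grid`` (must lie inside the range)."""
        grid = _as_grid(grid)
        if grid[0] < self.wavelengths[0] - 1e-9 or grid[-1] > self.wavelengths[-1] + 1e-9:
            raise GridMismatchError(
                "target grid extends beyond the recorded wavelength range"
            )
        counts = np.interp(grid, self.wavelengths, self.counts)
        return replace(self, wavelengths=grid, counts=counts)


@dataclass
class Spectrum:
    """Absorbance (or fluorescence) versus wavelength, with history and mask."""

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "absorbance"
    label: Any = None
    history: list[dict] = field(default_factory=list)
    mask: np.ndarray | None = None

    def __post_init__(self):
        wl = _as_grid(self.wavelengths)
        values = np.asarray(self.values, dtype=float)
        if values.shape != wl.shape:
            raise SpectrumFormatError("values and wavelengths differ in length")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.mask is None:
            mask = ~np.isfinite(values)
        else:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != wl.shape:
                raise SpectrumFormatError("mask and wavelengths differ in length")
            mask = mask | ~np.isfinite(values)
        self.wavelengths = wl
        self.values = values
        self.mask = mask
        self.history = list(self.history)

    def __len__(self) -> int:
        return self.wavelengths.size

    @property
    def valid(self) -> np.ndarray:
        """Boolean array, ``True`` where the point is usable."""
        return ~self.mask

    def with_values(self, values: np.ndarray, op: str | None = None,
                    mask: np.ndarray | None = None, **params) -> "Spectrum":
        """Copy with new values; append ``op`` (and its parameters) to history."""
        history = list(self.history)
        if op is not None:
            history.append({"op": op, **params})
        return Spectrum(
            wavelengths=self.wavelengths,
            values=np.asarray(values, dtype=float),
            kind=self.kind,
            label=self.label,
            history=history,
            mask=self.mask.copy() if mask is None else np.asarray(mask, bool),
        )

    def log(self, op: str, **params) -> None:
        """Append an operation record in place (history is append-only)."""
        self.history.append({"op": op, **params})

    def band_indices(self, band: tuple[float, float]) -> np.ndarray:
        """Indices of grid points inside the closed interval ``band`` (nm)."""
        lo, hi = min(band), max(band)
        return np.nonzero((self.wavelengths >= lo) & (self.wavelengths <= hi))[0]

    def resample(self, grid: np.ndarray) -> "Spectrum":
        grid = _as_grid(grid)
        if grid[0] < self.wavelengths[0] - 1e-9 or grid[-1] > self.wavelengths[-1] + 1e-9:
            raise GridMismatchError(
                "target grid extends beyond the recorded wavelength range"
            )
        vals = np.where(self.mask, np.nan, self.values)
        new = np.interp(grid, self.wavelengths, vals)
        return Spectrum(grid, new, kind=self.kind, label=self.label,
                        history=self.history + [{"op": "resample",
                                                 "n": int(grid.size)}])


@dataclass
class SpectrumSeries:
    """Ordered spectra on one shared grid, labelled by time, dose or index."""

    members: list[Spectrum]
    axis: str = "index"

    def __post_init__(self):
        if not self.members:
            raise ValueError("a series needs at least one member")
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        grid = self.members[0].wavelengths
        for m in self.members[1:]:
            if m.wavelengths.shape != grid.shape or not np.allclose(
                    m.wavelengths, grid, rtol=0, atol=1e-9):
                raise GridMismatchError(
                    "series members must share one wavelength grid "
                    "(resample at construction)")
        if self.axis in ("time", "dose"):
            labels = self.labels
            if np.any(~np.isfinite(labels)):
                raise ValueError(f"{self.axis} axis requires numeric labels")
            if np.any(np.diff(labels) <= 0):
                raise ValueError(
                    f"{self.axis} labels must be strictly increasing; "
                    f"got {labels.tolist()}")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.members)

    def __getitem__(self, i: int) -> Spectrum:
        return self.members[i]

    @property
    def wavelengths(self) -> np.ndarray:
        return self.members[0].wavelengths

    @property
    def labels(self) -> np.ndarray:
        return np.asarray(
            [np.nan if m.label is None or isinstance(m.label, str) else float(m.label)
             for m in self.members])

    def map(self, fn, op: str | None = None) -> "SpectrumSeries":
        """Apply ``fn`` to every member, returning a new series."""
        return SpectrumSeries([fn(m) for m in self.members], axis=self.axis)
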