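"""Reading and writing of spectrometer ASCII exports.

Fibre spectrometers (Ocean Optics, Avantes, JASCO, ...) export plain-text
two-column tables — wavelength and either raw detector counts or computed
absorbance — optionally preceded by free-form header lines.  Delimiters
vary (whitespace, tab, comma, semicolon), as does the decimal separator.
This module sniffs those dialects, normalizes everything onto
:class:`~icospec.core.RawTrace` / :class:`~icospec.core.Spectrum`, and
writes corrected spectra back out with their processing history in
``#``-prefixed header lines so a file fully documents how it was made.
"""

from __future__ import annotations

import ast
import glob as _glob
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core import (
    GridMismatchError,
    RawTrace,
    Spectrum,
    SpectrumFormatError,
    SpectrumSeries,
)

__all__ = ["read_trace", "write_spectrum", "read_series", "parse_filename_label"]

_NUMERIC_RE = re.compile(r"^[+-]?(\d+[.,]?\d*|[.,]\d+)([eE][+-]?\d+)?$")

_UNIT_SCALE = {"us": 1e-6, "µs": 1e-6, "ms": 1e-3, "s": 1.0, "gy": 1.0, "": 1.0}

# keywords that mark a header as declaring counts vs absorbance
_COUNT_WORDS = ("count", "intensity", "raw", "scope")
_ABS_WORDS = ("absorbance", "abs", "od", "optical density")


def _split_row(line: str) -> list[str]:
    """Split one data row on the most plausible delimiter."""
    line = line.strip()
    for delim in ("\t", ";", ","):
        if delim in line:
            parts = [p.strip() for p in line.split(delim) if p.strip()]
            # a comma may be a decimal separator, not a delimiter: if every
            # fragment is an integer-looking token and there are exactly 2
            # commas per 2 columns this is ambiguous; require fragments to
            # be numbers on their own to accept comma as delimiter
            if delim == "," and len(parts) == 2 and all(
                    "," not in p and _NUMERIC_RE.match(p) for p in parts):
                return parts
            if delim != ",":
                return parts
    return line.split()


def _to_float(token: str) -> float:
    token = token.strip()
    if _NUMERIC_RE.match(token) and "," in token and "." not in token:
        token = token.replace(",", ".")  # decimal comma
    return float(token)


def _is_numeric_row(parts: list[str]) -> bool:
    if len(parts) < 2:
        return False
    if not _NUMERIC_RE.match(parts[0]):
        return False
    return bool(_NUMERIC_RE.match(parts[1])) or parts[1].lower() in ("nan", "na")


def _parse_ascii(path: Path) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray | None]:
    """Return (header_lines, wavelengths, values, mask_or_None), sorted by λ."""
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc
    headers: list[str] = []
    wl, vals = [], []
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        parts = _split_row(stripped)
        if _is_numeric_row(parts):
            wl.append(_to_float(parts[0]))
            v = parts[1]
            vals.append(np.nan if v.lower() in ("nan", "na") else _to_float(v))
        else:
            headers.append(stripped)
    if len(wl) < 2:
        raise SpectrumFormatError(f"{path}: fewer than 2 numeric rows")
    wl_arr = np.asarray(wl)
    vals_arr = np.asarray(vals)
    order = np.argsort(wl_arr, kind="stable")
    wl_arr, vals_arr = wl_arr[order], vals_arr[order]
    dup = np.nonzero(np.diff(wl_arr) == 0)[0]
    if dup.size:
        raise SpectrumFormatError(
            f"{path}: duplicate wavelength {wl_arr[dup[0]]:g} nm")
    mask = ~np.isfinite(vals_arr)
    return headers, wl_arr, vals_arr, (mask if mask.any() else None)


def _sniff_kind(headers: list[str], values: np.ndarray) -> str:
    """Decide counts vs absorbance from headers, falling back on magnitude."""
    joined = " ".join(headers).lower()
    for w in _ABS_WORDS:
        if re.search(rf"\b{re.escape(w)}\b", joined):
            return "absorbance"
    for w in _COUNT_WORDS:
        if re.search(rf"\b{re.escape(w)}", joined):
            return "counts"
    finite = values[np.isfinite(values)]
    # absorbance of real samples stays within a few OD; counts reach 1e3-1e5
    return "counts" if finite.size and np.nanmax(np.abs(finite)) > 20 else "absorbance"


def _history_from_headers(headers: list[str]) -> list[dict]:
    hist = []
    for h in headers:
        m = re.match(r"#\s*history:\s*(.*)", h)
        if m:
            try:
                entry = ast.literal_eval(m.group(1))
                if isinstance(entry, dict):
                    hist.append(entry)
            except (ValueError, SyntaxError):
                pass
    return hist


def read_trace(path, dialect: str = "auto", role: str = "sample",
               as_: str = "auto"):
    """Read one ASCII export as a :class:`RawTrace` or :class:`Spectrum`.

    Parameters
    ----------
    path : str or Path
        Two-column ASCII file; non-numeric leading lines are treated as
        headers and preserved in ``source_id`` / history.
    dialect : {"auto", "two_column", "headered"}
        Layout hint; ``auto`` sniffs delimiter and header lines.
    role : {"sample", "reference", "background"}
        Role assigned when the file holds raw counts.
    as\\_ : {"auto", "counts", "absorbance"}
        Force the interpretation; ``auto`` sniffs header keywords and
        falls back on value magnitude.

    Returns
    -------
    RawTrace when the data are counts, Spectrum when absorbance.
    """
    if dialect not in ("auto", "two_column", "headered"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    headers, wl, vals, mask = _parse_ascii(path)
    if dialect == "two_column" and headers:
        raise SpectrumFormatError(
            f"{path}: dialect 'two_column' forbids header lines")
    kind = as_ if as_ != "auto" else _sniff_kind(headers, vals)
    if kind == "counts":
        return RawTrace(wl, np.where(np.isfinite(vals), vals, 0.0), role=role,
                        source_id="\n".join(headers) or str(path))
    label = None
    for h in headers:
        m = re.match(r"#\s*label:\s*(\S+)", h)
        if m:
            try:
                label = float(m.group(1))
            except ValueError:
                label = m.group(1)
    return Spectrum(wl, vals, kind="absorbance", label=label,
                    history=_history_from_headers(headers), mask=mask)


def write_spectrum(s: Spectrum, path) -> Path:
    """Write a spectrum as two-column ASCII with ``#`` history headers.

    Masked points are written as ``nan`` so the file round-trips exactly;
    values are written at full float precision (``repr``).
    """
    path = Path(path)
    lines = [f"# kind: {s.kind}"]
    if s.label is not None:
        lines.append(f"# label: {s.label}")
    for entry in s.history:
        lines.append(f"# history: {entry!r}")
    for w, v, m in zip(s.wavelengths, s.values, s.mask):
        lines.append(f"{float(w)!r}\t{'nan' if m else repr(float(v))}")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
    return path


def parse_filename_label(path) -> float:
    """Extract a numeric time/dose label from a filename stem.

    The last number in the stem is taken, with an optional unit suffix:
    ``us``/``µs`` (1e-6 s), ``ms`` (1e-3 s), ``s``, ``Gy``.  Examples:
    ``t_000003us.txt`` → 3e-6, ``t_1s.txt`` → 1.0, ``dose_40Gy.txt`` → 40.
    """
    stem = Path(path).stem
    matches = re.findall(r"(\d+(?:[.]\d+)?)\s*(us|µs|ms|s|gy)?", stem,
                         flags=re.IGNORECASE)
    if not matches:
        raise ValueError(f"no numeric label found in filename {stem!r}")
    num, unit = matches[-1]
    return float(num) * _UNIT_SCALE.get(unit.lower(), 1.0)


def _resolve_paths(paths) -> list[Path]:
    if isinstance(paths, (str, Path)):
        text = str(paths)
        if any(c in text for c in "*?["):
            found = sorted(_glob.glob(text))
            if not found:
                raise IOError(f"glob {text!r} matched no files")
            return [Path(p) for p in found]
        return [Path(text)]
    return [Path(p) for p in paths]


def read_series(paths, label_rule: str = "filename_number",
                labels: Sequence[float] | None = None,
                manifest=None, axis: str = "time") -> SpectrumSeries:
    """Read several spectra as one series on a common wavelength grid.

    Members are linearly interpolated onto the first file's grid restricted
    to the intersection of all wavelength ranges, then sorted by ascending
    label.  The pre-sort file order is recorded in each member's history.

    Parameters
    ----------
    paths : list of paths or a glob pattern
    label_rule : {"filename_number", "manifest", "explicit"}
    labels : explicit numeric labels (with ``label_rule="explicit"``)
    manifest : path to a two-column ASCII file (filename, label)
    axis : {"time", "dose", "index"}
    """
    files = _resolve_paths(paths)
    if not files:
        raise ValueError("need at least one file")
    if label_rule == "filename_number":
        lab = [parse_filename_label(p) for p in files]
    elif label_rule == "manifest":
        if manifest is None:
            raise ValueError("label_rule='manifest' requires a manifest path")
        table = {}
        for line in Path(manifest).read_text().splitlines():
            parts = line.split()
            if len(parts) >= 2 and not line.lstrip().startswith("#"):
                table[parts[0]] = float(parts[1])
        try:
            lab = [table[p.name] for p in files]
        except KeyError as exc:
            raise ValueError(f"manifest misses an entry for {exc}") from exc
    elif label_rule == "explicit":
        if labels is None or len(labels) != len(files):
            raise ValueError("explicit labels must match the number of files")
        lab = [float(x) for x in labels]
    else:
        raise ValueError(f"unknown label_rule {label_rule!r}")

    if len(files) == 1 and axis != "index":
        axis = "index"  # a single spectrum carries no kinetic axis

    if axis in ("time", "dose"):
        seen: dict[float, list[str]] = {}
        for p, l in zip(files, lab):
            seen.setdefault(l, []).append(p.name)
        dups = {l: ns for l, ns in seen.items() if len(ns) > 1}
        if dups:
            raise ValueError(f"duplicate labels: {dups}")

    specs = []
    for i, (p, l) in enumerate(zip(files, lab)):
        s = read_trace(p, as_="absorbance")
        s.label = l
        s.log("read_series_member", file=p.name, input_position=i)
        specs.append(s)

    lo = max(s.wavelengths[0] for s in specs)
    hi = min(s.wavelengths[-1] for s in specs)
    if lo >= hi:
        raise GridMismatchError(
            f"wavelength ranges are disjoint (common range [{lo:g}, {hi:g}])")
    base = specs[0].wavelengths
    grid = base[(base >= lo) & (base <= hi)]
    members = [s if s.wavelengths.shape == grid.shape
               and np.allclose(s.wavelengths, grid) else s.resample(grid)
               for s in specs]
    members.sort(key=lambda s: s.label)
    return SpectrumSeries(members, axis=axis)
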