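"""Domain types, file I/O, axis management and resampling.

The central objects are :class:`Spectrum` — one Raman trace (shift axis in
cm⁻¹ plus an intensity vector in arbitrary units) — and :class:`SpectrumSet`,
an ordered, labelled collection of spectra sharing one axis (a mapping
experiment, a synthetic batch, or a reference library group).

Files are plain text: two-column delimited traces (shift, intensity), wide
delimited tables (first column = shift axis, one spectrum per remaining
column), and read-only JCAMP-DX (``XYDATA=(X++(Y..Y))`` and ``XYPOINTS``
forms only). Window widths throughout the toolkit are configured in cm⁻¹ and
converted to point counts per-axis with :func:`cm1_to_points`, so files from
any instrument work regardless of point spacing.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .errors import (
    AxisError,
    DuplicateAxisError,
    EmptyInputError,
    FormatError,
    NoCommonRangeError,
    ParameterError,
    RamanStainsError,
    TooShortError,
)

#: Minimum number of points for a spectrum entering the toolkit via I/O or
#: public constructors. Internal reductions (block averaging) may go shorter.
MIN_POINTS = 8

_DELIMITERS = (",", "\t", ";", None)  # None = any whitespace; fixed sniff order


@dataclass(frozen=True)
class AxisSpec:
    """A uniform Raman-shift axis: ``start`` to ``stop`` cm⁻¹ at ``step`` cm⁻¹.

    The default covers the common fingerprint acquisition range
    400–1800 cm⁻¹ at 1.0 cm⁻¹ spacing (1401 points).
    """

    start: float = 400.0
    stop: float = 1800.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if not (self.start < self.stop):
            raise ParameterError(f"AxisSpec requires start < stop, got {self.start} >= {self.stop}")
        if not (self.step > 0):
            raise ParameterError(f"AxisSpec requires step > 0, got {self.step}")

    def grid(self) -> np.ndarray:
        """The axis as an array, inclusive of ``stop`` when it lands on the grid."""
        n = int(np.floor((self.stop - self.start) / self.step + 1e-9)) + 1
        return self.start + self.step * np.arange(n)


@dataclass(frozen=True)
class Spectrum:
    """One Raman trace: strictly increasing shift axis + intensity vector.

    Intensities may be negative (baseline-subtracted residuals dip below
    zero); both arrays must be finite and of equal length.
    """

    axis: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensity", intensity)
        if axis.ndim != 1 or intensity.ndim != 1:
            raise ParameterError("axis and intensity must be one-dimensional")
        if axis.shape != intensity.shape:
            raise ParameterError(
                f"axis ({axis.size}) and intensity ({intensity.size}) lengths differ"
            )
        if axis.size < MIN_POINTS:
            raise TooShortError(f"spectrum has {axis.size} points; minimum is {MIN_POINTS}")
        self._check_values(axis, intensity)

    @staticmethod
    def _check_values(axis: np.ndarray, intensity: np.ndarray) -> None:
        if not np.all(np.isfinite(axis)):
            raise ParameterError("axis contains non-finite values")
        if not np.all(np.isfinite(intensity)):
            raise ParameterError("intensity contains non-finite values")
        if axis.size >= 2 and not np.all(np.diff(axis) > 0):
            raise DuplicateAxisError("axis must be strictly increasing (sorted, no duplicates)")

    @classmethod
    def _unchecked(cls, axis: np.ndarray, intensity: np.ndarray, label: str = "") -> "Spectrum":
        """Construct without the minimum-length check (internal reductions only)."""
        obj = object.__new__(cls)
        object.__setattr__(obj, "axis", np.asarray(axis, dtype=float))
        object.__setattr__(obj, "intensity", np.asarray(intensity, dtype=float))
        object.__setattr__(obj, "label", label)
        cls._check_values(obj.axis, obj.intensity)
        return obj

    # -- conveniences -------------------------------------------------------

    @property
    def n_points(self) -> int:
        return int(self.axis.size)

    @property
    def step(self) -> float:
        """Median axis spacing in cm⁻¹."""
        return float(np.median(np.diff(self.axis)))

    def with_intensity(self, intensity: np.ndarray, label: str | None = None) -> "Spectrum":
        """A copy of this spectrum with a new intensity vector (same axis)."""
        return Spectrum(self.axis, np.asarray(intensity, dtype=float),
                        self.label if label is None else label)

    def area(self) -> float:
        """Trapezoidal integral of the intensity over the axis."""
        return float(np.trapezoid(self.intensity, self.axis))

    def same_axis(self, other: "Spectrum", rtol: float = 0.0, atol: float = 1e-9) -> bool:
        return self.axis.shape == other.axis.shape and np.allclose(
            self.axis, other.axis, rtol=rtol, atol=atol
        )

    def require_same_axis(self, other: "Spectrum") -> None:
        if not self.same_axis(other):
            raise AxisError(
                f"spectra {self.label!r} and {other.label!r} are not on the same axis"
            )


class SpectrumSet:
    """An ordered collection of spectra on one shared axis.

    Parameters
    ----------
    spectra : iterable of Spectrum
        Members; all axes must be identical element-wise and labels unique.
    group : str
        Category tag, e.g. ``"stain-on-substrate"``, ``"pure-substrate"``,
        ``"reference"``.
    metadata : dict, optional
        Free-form provenance (processing parameters, generator truth, ...).
    """

    def __init__(self, spectra: Iterable[Spectrum], group: str = "",
                 metadata: dict | None = None) -> None:
        members = list(spectra)
        if not members:
            raise EmptyInputError("a SpectrumSet needs at least one spectrum")
        axis = members[0].axis
        labels: set[str] = set()
        for s in members:
            if s.axis.shape != axis.shape or not np.array_equal(s.axis, axis):
                raise AxisError(
                    f"spectrum {s.label!r} is not on the shared axis of the set"
                )
            if s.label in labels:
                raise ParameterError(f"duplicate label {s.label!r} in SpectrumSet")
            labels.add(s.label)
        self.spectra: list[Spectrum] = members
        self.group = group
        self.metadata: dict = dict(metadata or {})

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]

    @property
    def axis(self) -> np.ndarray:
        return self.spectra[0].axis

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.spectra]

    def matrix(self) -> np.ndarray:
        """Intensities stacked row-wise: shape (n_spectra, n_points)."""
        return np.vstack([s.intensity for s in self.spectra])

    def mean_spectrum(self, label: str = "mean") -> Spectrum:
        """Pointwise arithmetic mean of the set."""
        return Spectrum(self.axis, self.matrix().mean(axis=0), label)

    def map(self, fn, group: str | None = None, **metadata) -> "SpectrumSet":
        """Apply ``fn`` to every member, keeping labels and group."""
        out = SpectrumSet([fn(s) for s in self.spectra],
                          self.group if group is None else group,
                          dict(self.metadata))
        out.metadata.update(metadata)
        return out


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _parse_two_column(path: Path) -> tuple[np.ndarray, np.ndarray]:
    xs: list[float] = []
    ys: list[float] = []
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields: list[str] | None = None
            for delim in _DELIMITERS:
                parts = [p for p in line.split(delim) if p != ""]
                if len(parts) >= 2:
                    fields = parts
                    break
            if fields is None or len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected two delimited columns")
            try:
                xs.append(float(fields[0]))
                ys.append(float(fields[1]))
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric value in {line!r}"
                ) from None
    return np.asarray(xs), np.asarray(ys)


_JCAMP_NUM = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")


def _parse_jcamp(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal JCAMP-DX reader: XYDATA=(X++(Y..Y)) and XYPOINTS=(XY..XY)."""
    header: dict[str, str] = {}
    mode = None
    data_lines: list[str] = []
    with open(path, "r") as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                value = value.strip()
                if key == "XYDATA":
                    mode = "xydata"
                    continue
                if key == "XYPOINTS":
                    mode = "xypoints"
                    continue
                if key == "END":
                    mode = None
                    continue
                header[key] = value
                mode = None if key not in ("XYDATA", "XYPOINTS") else mode
            elif mode is not None and line:
                data_lines.append(line)
    if not data_lines:
        raise FormatError(f"{path}: no XYDATA/XYPOINTS block found")
    xfac = float(header.get("XFACTOR", 1.0))
    yfac = float(header.get("YFACTOR", 1.0))
    xs: list[float] = []
    ys: list[float] = []
    for line in data_lines:
        nums = [float(t) for t in _JCAMP_NUM.findall(line)]
        if not nums:
            raise FormatError(f"{path}: unparseable JCAMP data line {line!r}")
        if len(nums) >= 2 and len(nums) % 2 == 0 and "," in line and ";" in line:
            # XYPOINTS pair style "x, y; x, y"
            for i in range(0, len(nums), 2):
                xs.append(nums[i] * xfac)
                ys.append(nums[i + 1] * yfac)
        else:
            # X++(Y..Y): first number is X of the first Y on the line
            x0 = nums[0]
            yvals = nums[1:]
            if "DELTAX" in header:
                dx = float(header["DELTAX"])
            elif "LASTX" in header and "FIRSTX" in header and "NPOINTS" in header:
                n = int(float(header["NPOINTS"]))
                dx = (float(header["LASTX"]) - float(header["FIRSTX"])) / max(n - 1, 1)
            else:
                raise FormatError(f"{path}: XYDATA block without DELTAX/LASTX information")
            for i, y in enumerate(yvals):
                xs.append((x0 + i * dx) * xfac)
                ys.append(y * yfac)
    return np.asarray(xs), np.asarray(ys)


def read_spectrum(path: str | os.PathLike, dialect: str = "two-column",
                  label: str | None = None) -> Spectrum:
    """Read one spectrum from a text file.

    Parameters
    ----------
    path : path
        File to read.
    dialect : {"two-column", "jcamp-dx"}
        ``"two-column"`` is delimited text (comma, tab, semicolon or
        whitespace; ``#`` comments skipped). ``"jcamp-dx"`` reads the
        ``XYDATA=(X++(Y..Y))`` and ``XYPOINTS`` forms.
    label : str, optional
        Label for the returned spectrum; defaults to the file stem.

    Returns
    -------
    Spectrum
        Sorted by ascending Raman shift.
    """
    p = Path(path)
    if not p.exists():
        raise FormatError(f"no such file: {p}")
    if dialect == "two-column":
        x, y = _parse_two_column(p)
    elif dialect == "jcamp-dx":
        x, y = _parse_jcamp(p)
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")
    if x.size < MIN_POINTS:
        raise TooShortError(f"{p}: {x.size} points parsed; minimum is {MIN_POINTS}")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if np.any(np.diff(x) == 0):
        raise DuplicateAxisError(f"{p}: duplicate Raman-shift values")
    return Spectrum(x, y, p.stem if label is None else label)


def write_spectrum(s: Spectrum, path: str | os.PathLike) -> None:
    """Write a spectrum as two-column comma-delimited text at full precision."""
    p = Path(path)
    try:
        with open(p, "w") as fh:
            if s.label:
                fh.write(f"# label: {s.label}\n")
            fh.write("# raman_shift_cm-1,intensity\n")
            for x, y in zip(s.axis, s.intensity):
                fh.write(f"{float(x)!r},{float(y)!r}\n")
    except OSError as exc:
        raise RamanStainsError(f"cannot write {p}: {exc}") from exc


def _read_wide_table(path: Path) -> list[Spectrum]:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    # Headerless numeric tables: pandas will have coerced the first data row
    # into column names; detect and re-read.
    try:
        [float(c) for c in df.columns]
        df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
        df.columns = ["raman_shift"] + [f"spectrum_{i}" for i in range(1, df.shape[1])]
    except (TypeError, ValueError):
        pass
    if df.shape[1] < 2:
        raise FormatError(f"{path}: wide table needs an axis column plus >= 1 spectrum")
    axis = df.iloc[:, 0].to_numpy(dtype=float)
    order = np.argsort(axis, kind="stable")
    axis = axis[order]
    if np.any(np.diff(axis) == 0):
        raise DuplicateAxisError(f"{path}: duplicate Raman-shift values")
    out = []
    for col in df.columns[1:]:
        y = df[col].to_numpy(dtype=float)[order]
        out.append(Spectrum(axis, y, str(col)))
    return out


def read_spectrum_set(path: str | os.PathLike, group: str = "") -> SpectrumSet:
    """Read a spectrum set from a wide table file or a directory of traces.

    Spectra with differing axes are linearly resampled onto the first
    spectrum's axis restricted to the intersection range; the resampling is
    recorded in ``metadata["resampled"]``.
    """
    p = Path(path)
    if p.is_dir():
        files = sorted(f for f in p.iterdir()
                       if f.is_file() and f.suffix.lower() in (".csv", ".txt", ".tsv", ".dat", ".jdx", ".dx"))
        if not files:
            raise EmptyInputError(f"{p}: no spectrum files found")
        spectra = [read_spectrum(f, dialect="jcamp-dx" if f.suffix.lower() in (".jdx", ".dx")
                                 else "two-column") for f in files]
    else:
        spectra = _read_wide_table(p)
    if not spectra:
        raise EmptyInputError(f"{p}: empty spectrum set")

    axes_equal = all(s.same_axis(spectra[0]) for s in spectra[1:])
    resampled = False
    if not axes_equal:
        lo = max(s.axis[0] for s in spectra)
        hi = min(s.axis[-1] for s in spectra)
        if lo >= hi:
            raise NoCommonRangeError(f"{p}: spectra share no common Raman-shift range")
        ref_axis = spectra[0].axis
        target = ref_axis[(ref_axis >= lo) & (ref_axis <= hi)]
        if target.size < MIN_POINTS:
            raise NoCommonRangeError(f"{p}: common range holds fewer than {MIN_POINTS} points")
        spectra = [Spectrum(target, np.interp(target, s.axis, s.intensity), s.label)
                   for s in spectra]
        resampled = True
    return SpectrumSet(spectra, group=group, metadata={"source": str(p), "resampled": resampled})


def write_spectrum_set(ss: SpectrumSet, path: str | os.PathLike) -> None:
    """Write a set as a wide comma-delimited table (column 1 = shift axis)."""
    df = pd.DataFrame({"raman_shift_cm-1": ss.axis})
    for s in ss:
        df[s.label or f"spectrum_{len(df.columns)}"] = s.intensity
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# axis utilities
# ---------------------------------------------------------------------------

def resample(s: Spectrum, target: AxisSpec | np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto a target axis (no extrapolation)."""
    grid = target.grid() if isinstance(target, AxisSpec) else np.asarray(target, dtype=float)
    if grid[0] < s.axis[0] - 1e-12 or grid[-1] > s.axis[-1] + 1e-12:
        raise AxisError(
            f"target range [{grid[0]}, {grid[-1]}] exceeds spectrum range "
            f"[{s.axis[0]}, {s.axis[-1]}] (extrapolation not supported)"
        )
    return Spectrum(grid, np.interp(grid, s.axis, s.intensity), s.label)


def cm1_to_points(width: float, axis: np.ndarray, odd: bool = False,
                  uniformity_rtol: float = 0.01) -> int:
    """Convert a window width in cm⁻¹ to a point count on a (uniform) axis.

    The count is ``round(width / median step)``, forced odd when ``odd`` is
    requested (smoothing windows), with a minimum of 3. E.g. on a
    0.911 cm⁻¹-step axis, 182.2 cm⁻¹ → 200 points and 41 cm⁻¹ → 45 points.
    """
    axis = np.asarray(axis, dtype=float)
    steps = np.diff(axis)
    if steps.size == 0:
        raise AxisError("axis too short to define a step")
    med = float(np.median(steps))
    if np.max(np.abs(steps - med)) > uniformity_rtol * med:
        raise AxisError(
            f"axis is non-uniform beyond {uniformity_rtol:.0%} relative step variation"
        )
    if width <= 0:
        raise ParameterError(f"window width must be positive, got {width}")
    n = int(round(width / med))
    if odd and n % 2 == 0:
        n += 1
    n = max(n, 3)
    return n
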