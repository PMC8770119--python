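"""Calibration-curve and annual-reference data structures with file I/O.

Two reference objects are distinguished:

* :class:`CalCurve` — a smoothed calibration curve (IntCal-style) on an
  integer AD-year grid, evaluated by linear interpolation.  Used for the
  stage-1 wiggle match.
* :class:`AnnualReference` — a truly annual-resolution 14C series
  (B2018-style), evaluated by exact year lookup.  Used for stage-2
  chi-square anchoring, where single-year structure is the signal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoverageError, FormatError
from .units import BP_DATUM

__all__ = [
    "CalCurve",
    "AnnualReference",
    "read_intcal",
    "write_intcal",
    "read_annual_reference",
    "write_annual_reference",
]


@dataclass(frozen=True)
class CalCurve:
    """Interpolated calibration curve: calendar year AD -> 14C age +- 1 sigma.

    ``grid`` holds ascending integer calendar years AD; ``age`` and
    ``sigma`` are the curve mean and 1-sigma uncertainty in 14C yr at each
    grid year.  Between grid years both the mean and sigma are linearly
    interpolated (the common convention; curve files do not define a
    between-node sigma).
    """

    grid: np.ndarray
    age: np.ndarray
    sigma: np.ndarray
    name: str = ""

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=int)
        age = np.asarray(self.age, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if grid.size == 0:
            raise FormatError("calibration curve is empty")
        if not (len(grid) == len(age) == len(sigma)):
            raise ValueError("grid, age and sigma must have equal length")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("curve grid must be strictly increasing")
        if np.any(sigma <= 0):
            raise ValueError("curve sigma must be positive everywhere")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "age", age)
        object.__setattr__(self, "sigma", sigma)

    @property
    def span(self) -> tuple[int, int]:
        """(first, last) calendar year AD covered by the curve."""
        return int(self.grid[0]), int(self.grid[-1])

    def at(self, years) -> tuple[np.ndarray, np.ndarray]:
        """Curve mean and sigma at calendar ``years`` (linear interpolation).

        Raises :class:`CoverageError` for years outside the curve span.
        """
        years = np.asarray(years, dtype=float)
        lo, hi = self.span
        outside = (years < lo) | (years > hi)
        if np.any(outside):
            missing = np.unique(years[outside]).astype(int)
            raise CoverageError(
                f"years outside curve span {lo}..{hi}: {missing.tolist()}",
                missing_years=missing.tolist(),
            )
        return np.interp(years, self.grid, self.age), np.interp(years, self.grid, self.sigma)


@dataclass(frozen=True)
class AnnualReference:
    """Single-year-resolution 14C reference series.

    ``year`` holds consecutive integer calendar years AD; ``age`` and
    ``sigma`` the per-year 14C age and its 1-sigma uncertainty.  Lookup is
    exact per year — no interpolation — because the annual structure (the
    single-year spike) is exactly what stage-2 matching relies on.
    """

    year: np.ndarray
    age: np.ndarray
    sigma: np.ndarray
    name: str = ""

    def __post_init__(self):
        year = np.asarray(self.year, dtype=int)
        age = np.asarray(self.age, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if year.size == 0:
            raise FormatError("annual reference is empty")
        if not (len(year) == len(age) == len(sigma)):
            raise ValueError("year, age and sigma must have equal length")
        if np.any(np.diff(year) != 1):
            raise ValueError("reference years must be consecutive with step 1")
        if np.any(sigma <= 0):
            raise ValueError("reference sigma must be positive")
        object.__setattr__(self, "year", year)
        object.__setattr__(self, "age", age)
        object.__setattr__(self, "sigma", sigma)

    @property
    def span(self) -> tuple[int, int]:
        return int(self.year[0]), int(self.year[-1])

    def at(self, years) -> tuple[np.ndarray, np.ndarray]:
        """Reference age and sigma at integer calendar ``years`` (exact lookup)."""
        years = np.asarray(years, dtype=int)
        lo, hi = self.span
        outside = (years < lo) | (years > hi)
        if np.any(outside):
            missing = np.unique(years[outside]).tolist()
            raise CoverageError(
                f"years outside reference span {lo}..{hi}: {missing}",
                missing_years=missing,
            )
        idx = years - lo
        return self.age[idx], self.sigma[idx]

    def to_curve(self, name: str | None = None) -> CalCurve:
        """View the annual series as a calibration curve (same values)."""
        return CalCurve(self.year, self.age, self.sigma, name=name or self.name)

    def smoothed(self, window: int = 5, name: str | None = None) -> CalCurve:
        """Centered moving-average copy, as a lower-resolution CalCurve.

        Emulates the attenuation of single-year features in decadal-style
        calibration curves relative to annual references.  Edge years use
        the partial window.
        """
        if window < 1:
            raise ValueError("window must be >= 1")
        age = pd.Series(self.age).rolling(window, center=True, min_periods=1).mean().to_numpy()
        sigma = pd.Series(self.sigma).rolling(window, center=True, min_periods=1).mean().to_numpy()
        return CalCurve(self.year, age, sigma, name=name or f"{self.name} (ma{window})")


_NUMERIC_SPLIT = re.compile(r"[,\s;]+")


def _parse_numeric_rows(path, n_required: int):
    """Parse a comment-tolerant whitespace/comma table; returns (rows, line numbers)."""
    rows, lines = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.strip()
            if not text or text.startswith("#"):
                continue
            parts = [p for p in _NUMERIC_SPLIT.split(text) if p]
            if len(parts) < n_required:
                raise FormatError(
                    f"{path}: line {lineno}: expected at least {n_required} "
                    f"columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts[:n_required]])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            lines.append(lineno)
    return rows, lines


def read_intcal(path, name: str | None = None) -> CalCurve:
    """Read a calibration curve in the IntCal distribution dialect.

    The dialect is: '#' comment lines, then rows of
    ``cal BP, 14C age BP, 1 sigma`` (comma or whitespace separated; any
    further columns, e.g. Delta14C, are ignored).  cal BP may run in either
    direction but must be strictly monotone.  The curve is converted to the
    AD axis (AD = 1950 - cal BP) and linearly interpolated onto a 1-year
    grid over the file's span.
    """
    rows, _ = _parse_numeric_rows(path, 3)
    if not rows:
        raise FormatError(f"{path}: no data rows (empty curve)")
    data = np.asarray(rows, dtype=float)
    calbp, age, sigma = data[:, 0], data[:, 1], data[:, 2]
    diffs = np.diff(calbp)
    if len(calbp) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise FormatError(f"{path}: cal BP column is not strictly monotone")
    years_ad = BP_DATUM - calbp
    order = np.argsort(years_ad)
    years_ad, age, sigma = years_ad[order], age[order], sigma[order]
    if len(years_ad) == 1:
        grid = np.array([int(round(years_ad[0]))])
        return CalCurve(grid, age, sigma, name=name or str(path))
    grid = np.arange(int(np.ceil(years_ad[0])), int(np.floor(years_ad[-1])) + 1)
    if grid.size == 0:
        raise FormatError(f"{path}: curve span contains no integer year")
    return CalCurve(
        grid,
        np.interp(grid, years_ad, age),
        np.interp(grid, years_ad, sigma),
        name=name or str(path),
    )


def write_intcal(curve: CalCurve, path) -> None:
    """Write a CalCurve in the IntCal distribution dialect (cal BP descending)."""
    with open(path, "w") as fh:
        fh.write(f"# {curve.name or 'calibration curve'}\n")
        fh.write("# cal BP, 14C age BP, 1 sigma\n")
        for year, age, sigma in zip(curve.grid[::-1], curve.age[::-1], curve.sigma[::-1]):
            fh.write(f"{BP_DATUM - int(year)},{age:.6g},{sigma:.6g}\n")


def read_annual_reference(path, name: str | None = None) -> AnnualReference:
    """Read an annual reference series from a 3-column table.

    Columns are calendar year AD, 14C age BP, 1 sigma; '#' comments and an
    optional one-line header are tolerated; separators may be commas or
    whitespace.
    """
    rows = []
    with open(path) as fh:
        raw_lines = fh.readlines()
    for lineno, raw in enumerate(raw_lines, start=1):
        text = raw.strip()
        if not text or text.startswith("#"):
            continue
        parts = [p for p in _NUMERIC_SPLIT.split(text) if p]
        if len(parts) < 3:
            raise FormatError(f"{path}: line {lineno}: expected 3 columns")
        try:
            rows.append([float(p) for p in parts[:3]])
        except ValueError:
            if not rows:  # header line
                continue
            raise FormatError(f"{path}: line {lineno}: non-numeric row") from None
    if not rows:
        raise FormatError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float)
    order = np.argsort(data[:, 0])
    data = data[order]
    return AnnualReference(
        data[:, 0].astype(int), data[:, 1], data[:, 2], name=name or str(path)
    )


def write_annual_reference(reference: AnnualReference, path) -> None:
    """Write an AnnualReference as headered CSV (year AD, 14C age, 1 sigma)."""
    pd.DataFrame(
        {
            "year": reference.year,
            "c14_age_bp": reference.age,
            "sigma": reference.sigma,
        }
    ).to_csv(path, index=False)
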