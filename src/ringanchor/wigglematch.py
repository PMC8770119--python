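"""Stage 1: calibration and fixed-gap wiggle matching on an exact year grid.

A tree-ring series with a preserved waney edge has known internal year
gaps: ring r grew in calendar year x + r, where x is the unknown
waney-edge (felling) year and r <= 0.  Conditional on x the per-ring
likelihoods are independent Gaussians against the calibration curve, so
the model has a single free parameter and the posterior for x can be
evaluated exactly on the 1-year grid — no MCMC is needed.  This is the
grid-exact equivalent of the D_Sequence construction in OxCal.

All probabilities are discrete per-year masses on the integer AD grid,
computed in log space and renormalized, so arbitrarily poor absolute fits
cannot underflow to an all-zero posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .curves import CalCurve
from .measurements import RingSeries

__all__ = ["PosteriorDensity", "calibrate", "wiggle_match", "sum_densities", "hpd"]

#: A date is flagged out-of-range when its residual against the curve
#: exceeds this many combined sigma everywhere on the grid.
_OUT_OF_RANGE_NSIGMA = 10.0


@dataclass(frozen=True)
class PosteriorDensity:
    """Discrete posterior over integer calendar years AD.

    ``p`` holds per-year probability mass (sums to 1); ``hpd95`` the 95%
    highest-posterior-density intervals as inclusive (first, last) year
    pairs.  ``warnings`` carries data-quality flags (e.g. an out-of-range
    date or an uninformative, flat posterior).
    """

    years: np.ndarray
    p: np.ndarray
    hpd95: tuple[tuple[int, int], ...] = ()
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        p = np.asarray(self.p, dtype=float)
        if years.size == 0:
            raise ValueError("posterior grid is empty")
        if len(years) != len(p):
            raise ValueError("years and p must have equal length")
        if np.any(np.diff(years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("probability mass must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probability mass must sum to 1, got {p.sum()}")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "hpd95", tuple(tuple(iv) for iv in self.hpd95))

    @property
    def mode(self) -> int:
        """Year of maximum posterior mass (earliest year on exact ties)."""
        return int(self.years[np.argmax(self.p)])

    def hpd(self, level: float) -> tuple[tuple[int, int], ...]:
        """Highest-posterior-density intervals at the given mass level."""
        return hpd(self.years, self.p, level)

    def bounding_interval(self, level: float = 0.95) -> tuple[int, int]:
        """(first, last) year of the union of HPD intervals at ``level``."""
        intervals = self.hpd95 if level == 0.95 and self.hpd95 else self.hpd(level)
        return intervals[0][0], intervals[-1][1]


def hpd(years, p, level: float) -> tuple[tuple[int, int], ...]:
    """Smallest set of grid years holding >= ``level`` mass, as intervals.

    Years are taken in order of descending mass (ties broken toward the
    earlier year) until the cumulative mass reaches ``level``, then merged
    into maximal runs of consecutive years.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    years = np.asarray(years, dtype=int)
    p = np.asarray(p, dtype=float)
    # lexsort: primary key descending mass, secondary ascending year
    order = np.lexsort((years, -p))
    csum = np.cumsum(p[order])
    n_keep = int(np.searchsorted(csum, level - 1e-12)) + 1
    n_keep = min(n_keep, len(years))
    chosen = np.sort(years[order[:n_keep]])
    intervals = []
    start = prev = int(chosen[0])
    for y in chosen[1:]:
        y = int(y)
        if y == prev + 1:
            prev = y
        else:
            intervals.append((start, prev))
            start = prev = y
    intervals.append((start, prev))
    return tuple(intervals)


def _finalize(years: np.ndarray, loglik: np.ndarray, warnings: list[str]) -> PosteriorDensity:
    logz = logsumexp(loglik)
    p = np.exp(loglik - logz)
    p /= p.sum()
    if np.ptp(loglik) < 1e-12 and len(years) > 1:
        warnings.append("flat-posterior: data do not discriminate between years")
    return PosteriorDensity(years, p, hpd95=hpd(years, p, 0.95), warnings=tuple(warnings))


def _trial_years(curve: CalCurve, trial, ring_lo: int = 0, ring_hi: int = 0) -> np.ndarray:
    """Integer trial grid for x such that every ring year x + r stays on the curve."""
    lo, hi = curve.span
    x_lo, x_hi = lo - ring_lo, hi - ring_hi
    if trial is not None:
        x_lo, x_hi = max(x_lo, int(trial[0])), min(x_hi, int(trial[1]))
    if x_hi < x_lo:
        raise ValueError(
            f"empty trial window: rings {ring_lo}..{ring_hi} do not fit the "
            f"curve span {lo}..{hi} within the requested interval"
        )
    return np.arange(x_lo, x_hi + 1)


def calibrate(age: float, sigma: float, curve: CalCurve, trial=None) -> PosteriorDensity:
    """Calibrate a single 14C date against a curve.

    Posterior mass per grid year theta:
    p(theta) ∝ exp(-(age - C(theta))^2 / (2 (sigma^2 + dC(theta)^2))),
    with a flat prior over the grid (optionally restricted to ``trial``).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    years = _trial_years(curve, trial)
    mu, s_curve = curve.at(years)
    var = sigma**2 + s_curve**2
    z2 = (age - mu) ** 2 / var
    warnings = []
    if np.min(z2) > _OUT_OF_RANGE_NSIGMA**2:
        warnings.append(
            f"out-of-range: date {age:.0f}+-{sigma:.0f} BP is more than "
            f"{_OUT_OF_RANGE_NSIGMA:.0f} sigma from the curve everywhere"
        )
    return _finalize(years, -0.5 * z2, warnings)


def wiggle_match(series: RingSeries, curve: CalCurve, trial=None) -> PosteriorDensity:
    """Posterior for the waney-edge year x of a ring series.

    Joint likelihood over rings (ring r grew in year x + r, r <= 0):

        p(x) ∝ prod_i exp(-(R_i - C(x + r_i))^2 /
                          (2 (dR_i^2 + dC(x + r_i)^2)))

    with a flat prior on x over the trial window (default: every x for
    which all ring years lie on the curve).  Computed in log space and
    normalized, so the result is exact up to floating point even when the
    absolute fit is poor.
    """
    ring_lo, ring_hi = series.ring_span
    years = _trial_years(curve, trial, ring_lo, ring_hi)
    # ring years: (n_trial, n_rings)
    ring_years = years[:, None] + series.ring_index[None, :]
    mu, s_curve = curve.at(ring_years)
    var = series.sigma[None, :] ** 2 + s_curve**2
    loglik = -0.5 * np.sum((series.age[None, :] - mu) ** 2 / var, axis=1)
    warnings = []
    per_ring_best = np.min((series.age[None, :] - mu) ** 2 / var, axis=0)
    if np.any(per_ring_best > _OUT_OF_RANGE_NSIGMA**2):
        bad = series.ring_index[per_ring_best > _OUT_OF_RANGE_NSIGMA**2]
        warnings.append(
            f"out-of-range rings (no trial year within "
            f"{_OUT_OF_RANGE_NSIGMA:.0f} sigma): {bad.tolist()}"
        )
    return _finalize(years, loglik, warnings)


def sum_densities(densities) -> PosteriorDensity:
    """Normalized arithmetic mean of posteriors (the OxCal-style Sum).

    Inputs on different integer-year grids are aligned onto the union grid
    with zero fill; a warning is attached when any pair of grids is
    disjoint.
    """
    densities = list(densities)
    if not densities:
        raise ValueError("cannot sum an empty list of densities")
    lo = min(int(d.years[0]) for d in densities)
    hi = max(int(d.years[-1]) for d in densities)
    grid = np.arange(lo, hi + 1)
    total = np.zeros_like(grid, dtype=float)
    warnings: list[str] = []
    for d in densities:
        aligned = np.zeros_like(grid, dtype=float)
        aligned[d.years - lo] = d.p
        total += aligned
    overlap = all(
        min(int(a.years[-1]), int(b.years[-1])) >= max(int(a.years[0]), int(b.years[0]))
        for a in densities
        for b in densities
    )
    if not overlap:
        warnings.append("disjoint-grids: inputs were zero-filled onto the union grid")
    p = total / total.sum()
    return PosteriorDensity(grid, p, hpd95=hpd(grid, p, 0.95), warnings=tuple(warnings))
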