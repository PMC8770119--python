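"""Stage 2: exact-year anchoring by chi-square pattern matching.

A single-year cosmic-ray spike (Miyake event) in the atmospheric 14C
record acts as an absolute calendar anchor: once the ring containing the
event is identified, counting rings to the waney edge gives the felling
year exactly.  The identification is a classical chi-square match of the
per-ring 14C ages against an annual-resolution reference series, scanned
over trial waney-edge years:

    chi2(x) = sum_i (R_i - C(x + r_i))^2 / (dR_i^2 + dC(x + r_i)^2)

where R_i +- dR_i is the measurement of ring r_i and C +- dC the annual
reference.  Ring indices here are <= 0 with the waney edge at 0, so ring
r grew in year x + r; the same formula is often written C(x - r_i) with
positive ring counts — the two conventions are equivalent.

No vertical offset between sample and reference is fitted: the only free
parameter is the trial year x, so a match over n rings carries n - 1
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .curves import AnnualReference
from .errors import CoverageError
from .measurements import RingSeries

__all__ = [
    "MatchProfile",
    "chi_square",
    "chi_square_profile",
    "chi2_quantile",
    "anomaly_ring_window",
    "pad_ring_window",
    "date_waney_edge",
]


def chi2_quantile(level: float, dof: int) -> float:
    """Chi-square critical value: inverse CDF at ``level`` with ``dof`` d.f.

    chi2_quantile(0.95, 5) = 11.07, the conventional 95% acceptance
    threshold for a six-ring match.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if dof < 1:
        raise ValueError(f"dof must be >= 1, got {dof}")
    return float(stats.chi2.ppf(level, dof))


def chi_square(series: RingSeries, reference: AnnualReference, x: int) -> float:
    """Chi-square of a ring series against the reference at trial year ``x``.

    Exact evaluation of the matching statistic above; every ring year
    x + r must lie within the reference span (otherwise a
    :class:`CoverageError` lists the offending rings).
    """
    years = int(x) + series.ring_index
    lo, hi = reference.span
    outside = (years < lo) | (years > hi)
    if np.any(outside):
        raise CoverageError(
            f"{series.item_id}: trial year {x} puts rings "
            f"{series.ring_index[outside].tolist()} outside the reference "
            f"span {lo}..{hi}",
            missing_years=years[outside].tolist(),
        )
    ref_age, ref_sigma = reference.at(years)
    return float(
        np.sum((series.age - ref_age) ** 2 / (series.sigma**2 + ref_sigma**2))
    )


@dataclass(frozen=True)
class MatchProfile:
    """Chi-square scan over trial waney-edge years.

    ``accepted`` is the set of trial years passing the chi-square test at
    the stated level (chi2 <= critical); ``best_year`` is the argmin.  On
    an exact tie of the minimum the earliest year is reported and
    ``tied`` is set.
    """

    trial_years: np.ndarray
    chi2: np.ndarray
    dof: int
    level: float
    critical: float
    best_year: int
    accepted: tuple[int, ...]
    tied: bool = False
    n_rings: int = 0

    def __post_init__(self):
        years = np.asarray(self.trial_years, dtype=int)
        chi2 = np.asarray(self.chi2, dtype=float)
        if len(years) != len(chi2):
            raise ValueError("trial_years and chi2 must have equal length")
        if np.any(chi2 < 0):
            raise ValueError("chi2 values must be nonnegative")
        if self.best_year not in years:
            raise ValueError("best_year must be one of the trial years")
        object.__setattr__(self, "trial_years", years)
        object.__setattr__(self, "chi2", chi2)
        object.__setattr__(self, "accepted", tuple(int(y) for y in self.accepted))

    @property
    def best_chi2(self) -> float:
        return float(self.chi2[list(self.trial_years).index(self.best_year)])

    def to_dict(self) -> dict:
        return {
            "trial_years": self.trial_years.tolist(),
            "chi2": [round(v, 6) for v in self.chi2.tolist()],
            "dof": self.dof,
            "level": self.level,
            "critical": round(self.critical, 4),
            "best_year": self.best_year,
            "best_chi2": round(self.best_chi2, 6),
            "accepted": list(self.accepted),
            "tied": self.tied,
            "n_rings": self.n_rings,
        }


def chi_square_profile(
    series: RingSeries,
    reference: AnnualReference,
    trial: tuple[int, int],
    level: float = 0.95,
    rings: tuple[int, int] | None = None,
) -> MatchProfile:
    """Scan chi-square over trial waney-edge years and build the acceptance set.

    Parameters
    ----------
    series:
        Combined per-ring measurements for one item.
    reference:
        Annual-resolution reference series.
    trial:
        Inclusive (first, last) trial waney-edge year AD.
    level:
        Acceptance probability for the chi-square test (default 0.95).
    rings:
        Optional inclusive (lo, hi) ring-index window; only those rings
        enter the match (e.g. the window expected to contain the event).

    Degrees of freedom are n - 1 for n matched rings — one parameter (the
    trial year) is estimated from the scan.
    """
    if rings is not None:
        series = series.subset(*rings)
    n = len(series)
    if n < 2:
        raise ValueError("chi-square matching needs at least 2 rings (dof >= 1)")
    lo, hi = int(trial[0]), int(trial[1])
    if hi < lo:
        raise ValueError(f"empty trial window {trial}")
    years = np.arange(lo, hi + 1)
    values = np.array([chi_square(series, reference, int(x)) for x in years])
    dof = n - 1
    critical = chi2_quantile(level, dof)
    best_idx = int(np.argmin(values))  # argmin returns the first = earliest year
    tied = bool(np.sum(values == values[best_idx]) > 1)
    accepted = tuple(int(y) for y in years[values <= critical])
    return MatchProfile(
        trial_years=years,
        chi2=values,
        dof=dof,
        level=level,
        critical=critical,
        best_year=int(years[best_idx]),
        accepted=accepted,
        tied=tied,
        n_rings=n,
    )


def anomaly_ring_window(
    waney_interval: tuple[int, int], event_year: int
) -> tuple[int, int]:
    """Ring-index window that must contain the event ring.

    If the waney edge falls in year W, the ring grown in ``event_year``
    has index event_year - W (<= 0).  For a waney-edge interval
    [W_lo, W_hi] the event ring therefore lies in
    [event_year - W_hi, event_year - W_lo]; e.g. a stage-1 window of
    AD 1019-1024 with the AD 993 event gives rings -31..-26.
    """
    w_lo, w_hi = int(waney_interval[0]), int(waney_interval[1])
    if w_hi < w_lo:
        raise ValueError(f"invalid waney interval {waney_interval}")
    if event_year >= w_lo:
        raise ValueError(
            f"event year {event_year} is not strictly before the waney "
            f"interval {waney_interval} (event after felling)"
        )
    return (event_year - w_hi, event_year - w_lo)


def pad_ring_window(
    window: tuple[int, int], min_size: int, ring_span: tuple[int, int]
) -> tuple[int, int] | None:
    """Clip a ring window to an item's preserved span, then widen to ``min_size``.

    A sharp stage-1 bound can yield an event window of only one or two
    rings, which either leaves no degrees of freedom for the chi-square
    test or places every matched ring on one side of the spike boundary
    (little power against late trial years).  The window is therefore
    widened one ring at a time, alternating sides starting with the older
    (inner) side, until it holds ``min_size`` rings or the span is
    exhausted; a window already >= ``min_size`` is returned unchanged.
    Returns None when the window lies entirely outside the span (the item
    does not preserve the event rings).
    """
    s_lo, s_hi = int(ring_span[0]), int(ring_span[1])
    lo, hi = max(int(window[0]), s_lo), min(int(window[1]), s_hi)
    if hi < lo:
        return None
    grow_older = True
    while hi - lo + 1 < min_size and (lo > s_lo or hi < s_hi):
        if (grow_older or hi >= s_hi) and lo > s_lo:
            lo -= 1
        else:
            hi += 1
        grow_older = not grow_older
    return lo, hi


def date_waney_edge(anomaly_ring_index: int, event_year: int) -> int:
    """Felling (waney-edge) year once the event ring is identified.

    Counting |ring index| rings outward from the event ring reaches the
    waney edge: felling year = event_year - anomaly_ring_index.  A drop
    first visible when ring -29 sits at AD 992 (event onset AD 993 in ring
    -28) corresponds to felling in AD 1021.
    """
    if anomaly_ring_index > 0:
        raise ValueError(f"ring index must be <= 0, got {anomaly_ring_index}")
    return int(event_year) - int(anomaly_ring_index)
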