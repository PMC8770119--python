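"""Per-ring measurement data model, replicate combination, lab offsets.

Ring numbering follows the dendrochronological sampling convention for
timbers with a preserved waney edge: the waney edge (final growth ring,
felling year) is ring 0, the penultimate ring is -1, and so on inward.
A ring with index r in an item felled in year x therefore grew in
calendar year x + r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, PairingError

__all__ = [
    "RingMeasurement",
    "RingSeries",
    "ReplicateCombination",
    "LabOffset",
    "combine_replicates",
    "lab_offset",
    "series_from_measurements",
    "read_measurements",
    "write_measurements",
]


@dataclass(frozen=True)
class RingMeasurement:
    """One AMS determination of one tree ring.

    ``age`` and ``sigma`` are the conventional 14C age BP and its quoted
    1-sigma uncertainty in 14C yr.
    """

    item_id: str
    ring_index: int
    age: float
    sigma: float
    lab: str = ""
    sample_id: str = ""

    def __post_init__(self):
        if self.ring_index > 0:
            raise ValueError(
                f"ring_index must be <= 0 (waney edge = 0), got {self.ring_index}"
            )
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class ReplicateCombination:
    """Inverse-variance combination of replicate determinations of one ring.

    ``t_statistic`` is the Ward–Wilson consistency statistic
    T = sum_i w_i (R_i - Rbar)^2 with w_i = 1/sigma_i^2, which under
    replicate agreement follows chi-square with ``dof`` = n - 1 degrees of
    freedom (0 and T = 0 for a single measurement).
    """

    age: float
    sigma: float
    n: int
    t_statistic: float
    dof: int

    def consistent(self, level: float = 0.95) -> bool:
        """True when T does not exceed the chi-square critical value at ``level``."""
        if self.dof == 0:
            return True
        return self.t_statistic <= stats.chi2.ppf(level, self.dof)


def combine_replicates(group) -> ReplicateCombination:
    """Combine replicate measurements of one ring by inverse-variance weighting.

    All measurements must share item_id and ring_index.  The combined age
    is the weighted mean, combined sigma is (sum w_i)^(-1/2), and the
    Ward–Wilson T statistic quantifies replicate consistency.
    """
    group = list(group)
    if not group:
        raise ValueError("cannot combine an empty replicate group")
    keys = {(m.item_id, m.ring_index) for m in group}
    if len(keys) > 1:
        raise ValueError(f"replicates span multiple rings: {sorted(keys)}")
    if len(group) == 1:
        only = group[0]
        return ReplicateCombination(only.age, only.sigma, 1, 0.0, 0)
    ages = np.array([m.age for m in group])
    weights = np.array([1.0 / m.sigma**2 for m in group])
    mean = float(np.sum(weights * ages) / np.sum(weights))
    sigma = float(1.0 / math.sqrt(np.sum(weights)))
    t = float(np.sum(weights * (ages - mean) ** 2))
    return ReplicateCombination(mean, sigma, len(group), t, len(group) - 1)


@dataclass(frozen=True)
class RingSeries:
    """One wood item's combined per-ring 14C time series.

    ``ring_index`` is sorted ascending (innermost ring first, waney edge
    last when present); indices are unique.
    """

    item_id: str
    ring_index: np.ndarray
    age: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        rings = np.asarray(self.ring_index, dtype=int)
        age = np.asarray(self.age, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if rings.size == 0:
            raise ValueError("RingSeries must be nonempty")
        if not (len(rings) == len(age) == len(sigma)):
            raise ValueError("ring_index, age and sigma must have equal length")
        order = np.argsort(rings)
        rings, age, sigma = rings[order], age[order], sigma[order]
        if np.any(np.diff(rings) == 0):
            raise ValueError("ring indices must be unique")
        if np.any(rings > 0):
            raise ValueError("ring indices must be <= 0 (waney edge = 0)")
        if np.any(sigma <= 0):
            raise ValueError("sigma must be positive")
        object.__setattr__(self, "ring_index", rings)
        object.__setattr__(self, "age", age)
        object.__setattr__(self, "sigma", sigma)

    def __len__(self) -> int:
        return len(self.ring_index)

    @property
    def ring_span(self) -> tuple[int, int]:
        """(innermost, outermost) ring index present."""
        return int(self.ring_index[0]), int(self.ring_index[-1])

    def subset(self, ring_lo: int, ring_hi: int) -> "RingSeries":
        """Rings with ring_lo <= index <= ring_hi (raises if none present)."""
        mask = (self.ring_index >= ring_lo) & (self.ring_index <= ring_hi)
        if not np.any(mask):
            raise ValueError(
                f"{self.item_id}: no rings in window {ring_lo}..{ring_hi}"
            )
        return RingSeries(
            self.item_id, self.ring_index[mask], self.age[mask], self.sigma[mask]
        )


def series_from_measurements(measurements) -> dict[str, RingSeries]:
    """Group measurements by item, combine replicates per ring, build series.

    Returns a dict item_id -> RingSeries with one combined determination
    per ring index.
    """
    by_ring: dict[tuple[str, int], list[RingMeasurement]] = {}
    for m in measurements:
        by_ring.setdefault((m.item_id, m.ring_index), []).append(m)
    by_item: dict[str, dict[int, ReplicateCombination]] = {}
    for (item, ring), group in by_ring.items():
        by_item.setdefault(item, {})[ring] = combine_replicates(group)
    out = {}
    for item, rings in sorted(by_item.items()):
        idx = np.array(sorted(rings))
        out[item] = RingSeries(
            item,
            idx,
            np.array([rings[r].age for r in idx]),
            np.array([rings[r].sigma for r in idx]),
        )
    return out


@dataclass(frozen=True)
class LabOffset:
    """Weighted-mean inter-laboratory offset (lab_b minus lab_a), in 14C yr."""

    offset: float
    sigma: float
    n_pairs: int
    lab_a: str
    lab_b: str

    @property
    def significant(self) -> bool:
        """True when |offset| exceeds 2 sigma (a conventional significance screen)."""
        return abs(self.offset) > 2.0 * self.sigma


def lab_offset(measurements, lab_a: str, lab_b: str) -> LabOffset:
    """Estimate the systematic offset between two labs from shared rings.

    For every (item, ring) measured by both labs, within-lab replicates are
    first combined; the per-ring difference d = lab_b - lab_a carries
    variance sigma_a^2 + sigma_b^2.  The offset is the inverse-variance
    weighted mean of the differences, with 1-sigma (sum w)^(-1/2).

    Raises :class:`PairingError` if fewer than two shared rings exist.
    """
    by_ring: dict[tuple[str, int], dict[str, list[RingMeasurement]]] = {}
    for m in measurements:
        if m.lab in (lab_a, lab_b):
            by_ring.setdefault((m.item_id, m.ring_index), {}).setdefault(
                m.lab, []
            ).append(m)
    diffs, variances = [], []
    for key in sorted(by_ring):
        labs = by_ring[key]
        if lab_a in labs and lab_b in labs:
            a = combine_replicates(labs[lab_a])
            b = combine_replicates(labs[lab_b])
            diffs.append(b.age - a.age)
            variances.append(a.sigma**2 + b.sigma**2)
    if len(diffs) < 2:
        raise PairingError(
            f"need >= 2 rings measured by both {lab_a!r} and {lab_b!r}; "
            f"found {len(diffs)}"
        )
    w = 1.0 / np.asarray(variances)
    offset = float(np.sum(w * np.asarray(diffs)) / np.sum(w))
    sigma = float(1.0 / math.sqrt(np.sum(w)))
    return LabOffset(offset, sigma, len(diffs), lab_a, lab_b)


_REQUIRED_COLUMNS = ("item_id", "ring_index", "c14_age_bp", "sigma")


def read_measurements(path) -> list[RingMeasurement]:
    """Read per-ring measurements from headered CSV.

    Required columns: item_id, ring_index, c14_age_bp, sigma.  Optional:
    lab, sample_id.
    """
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    out = []
    for _, row in frame.iterrows():
        out.append(
            RingMeasurement(
                item_id=str(row["item_id"]),
                ring_index=int(row["ring_index"]),
                age=float(row["c14_age_bp"]),
                sigma=float(row["sigma"]),
                lab="" if "lab" not in frame.columns or pd.isna(row.get("lab")) else str(row["lab"]),
                sample_id=""
                if "sample_id" not in frame.columns or pd.isna(row.get("sample_id"))
                else str(row["sample_id"]),
            )
        )
    return out


def write_measurements(measurements, path) -> None:
    """Write measurements as headered CSV in the package schema."""
    pd.DataFrame(
        {
            "item_id": [m.item_id for m in measurements],
            "ring_index": [m.ring_index for m in measurements],
            "c14_age_bp": [m.age for m in measurements],
            "sigma": [m.sigma for m in measurements],
            "lab": [m.lab for m in measurements],
            "sample_id": [m.sample_id for m in measurements],
        }
    ).to_csv(path, index=False)
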