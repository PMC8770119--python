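"""Isotope-scale conventions and unit conversions.

Conventional radiocarbon ages follow the standard reporting conventions:
ages are computed with the Libby mean life (8033 yr), normalized to
delta13C = -25 permil, and quoted in years BP, i.e. relative to AD 1950.
The calendar axis used throughout the package is the integer astronomical
AD year; cal BP = 1950 - AD.
"""

from __future__ import annotations

import math

#: Conventional-age decay constant (yr).  This is the historical Libby
#: mean life, retained by convention for conventional ages; it is not the
#: physically current mean life of 14C.
LIBBY_MEAN_LIFE = 8033.0

#: Reference year of the BP scale: cal BP = BP_DATUM - year AD.
BP_DATUM = 1950


def ad_to_calbp(year):
    """Convert a calendar year AD to cal BP.  Involution with calbp_to_ad."""
    return BP_DATUM - year


def calbp_to_ad(calbp):
    """Convert cal BP to a calendar year AD."""
    return BP_DATUM - calbp


def delta_to_age_shift(delta: float) -> float:
    """Conventional-age shift equivalent to a permil activity change.

    A rise of ``delta`` permil in atmospheric 14C activity lowers the
    conventional 14C age of contemporaneous material.  The returned value

        shift = 8033 * ln(1 + delta/1000)

    is the magnitude of that age *drop* in 14C yr (positive for a rise in
    activity): subtract it from the no-event age to obtain the post-event
    age.  A 9 permil single-year production spike therefore manifests as a
    drop of about 70 14C yr.

    Raises
    ------
    ValueError
        If ``delta <= -1000`` (activity cannot be negative).
    """
    if delta <= -1000.0:
        raise ValueError(f"delta must exceed -1000 permil, got {delta}")
    return LIBBY_MEAN_LIFE * math.log1p(delta / 1000.0)


def f14c_to_age(f: float) -> float:
    """Conventional 14C age BP from a normalized activity ratio F14C."""
    if f <= 0:
        raise ValueError(f"F14C must be positive, got {f}")
    return -LIBBY_MEAN_LIFE * math.log(f)


def age_to_f14c(age: float) -> float:
    """Normalized activity ratio F14C from a conventional 14C age BP."""
    return math.exp(-age / LIBBY_MEAN_LIFE)


def delta13c(ratio_sample: float, ratio_standard: float) -> float:
    """Stable-isotope delta value in permil.

    delta13C = ((R_sample / R_standard) - 1) * 1000, with R the 13C/12C
    ratio.  Conventional ages are normalized to delta13C = -25 permil.
    """
    if ratio_sample <= 0 or ratio_standard <= 0:
        raise ValueError("isotope ratios must be positive")
    return (ratio_sample / ratio_standard - 1.0) * 1000.0


def round_to(value: float, step: float) -> float:
    """Round ``value`` to the nearest multiple of ``step``.

    Used for reporting spike magnitudes at the conventional "about"
    precision (nearest ten 14C yr); full precision is kept internally.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    return round(value / step) * step
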