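"""Radioactivity bookkeeping.

All downstream calculations assume activities expressed in Bq and
decay-corrected back to a single reference date (the day the soil or
fertilizer was labeled).  This module provides the correction factor,
the correction itself, and the specific-activity quotient that every
partitioning formula is built on.

Unit conventions used package-wide: activity in Bq, P masses in mg,
soil basis kg dry soil, specific activity in Bq per mg P.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Union

from .errors import ChronologyError, InvalidParameterError

#: default half-life (days) of the tracer isotope; configurable via
#: the ``half_life_days`` config key.
P33_HALF_LIFE_DAYS = 25.383

DateLike = Union[float, int, str, _dt.date, _dt.datetime]


def _as_date(value: DateLike):
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    if isinstance(value, str):
        return _dt.date.fromisoformat(value)
    raise TypeError(f"cannot interpret {value!r} as a date or day count")


def elapsed_days(count_date: DateLike, reference_date: DateLike = 0.0) -> float:
    """Days elapsed between the reference date and the count date.

    Both arguments accept either calendar dates (``datetime.date``,
    ISO-8601 strings) or plain day counts; mixing the two styles is an
    error.
    """
    c, r = _as_date(count_date), _as_date(reference_date)
    if isinstance(c, float) != isinstance(r, float):
        raise TypeError("count_date and reference_date must both be dates or both day counts")
    if isinstance(c, float):
        return c - r
    return (c - r).days + 0.0


@dataclass(frozen=True)
class ActivityMeasurement:
    """A raw scintillation reading awaiting decay correction.

    Parameters
    ----------
    raw_activity : float
        Measured activity in Bq (per pot, per mL, or per extract as
        context dictates). Must be >= 0.
    count_date : date-like or float
        When the reading was taken; a calendar date or days since the
        reference.
    reference_date : date-like or float, default 0
        The labeling date all activities are corrected back to.
    """

    raw_activity: float
    count_date: DateLike
    reference_date: DateLike = 0.0

    def __post_init__(self):
        if self.raw_activity < 0:
            raise InvalidParameterError(f"raw_activity must be >= 0, got {self.raw_activity}")

    @property
    def elapsed_days(self) -> float:
        return elapsed_days(self.count_date, self.reference_date)


@dataclass(frozen=True)
class SpecificActivity:
    """Activity per unit P mass (Bq per mg P)."""

    value: float
    activity: float
    p_mass: float


def decay_factor(elapsed_days: float, half_life_days: float = P33_HALF_LIFE_DAYS) -> float:
    """Back-correction multiplier ``2**(elapsed / half_life)``.

    Multiplying a measured activity by this factor restores the
    activity present at the reference date.
    """
    if half_life_days <= 0:
        raise InvalidParameterError(f"half_life_days must be > 0, got {half_life_days}")
    if elapsed_days < 0:
        raise ChronologyError(f"elapsed_days must be >= 0, got {elapsed_days}")
    return 2.0 ** (elapsed_days / half_life_days)


def decay_correct(meas: ActivityMeasurement, half_life_days: float = P33_HALF_LIFE_DAYS) -> float:
    """Activity (Bq) at the reference date implied by a raw reading."""
    dt = meas.elapsed_days
    if dt < 0:
        raise ChronologyError(
            f"count_date {meas.count_date!r} precedes reference_date {meas.reference_date!r}"
        )
    return meas.raw_activity * decay_factor(dt, half_life_days)


def specific_activity(activity: float, p_mass: float) -> SpecificActivity:
    """Specific activity of a pool: decay-corrected Bq over mg P."""
    if p_mass <= 0:
        raise InvalidParameterError(f"p_mass must be > 0, got {p_mass}")
    if activity < 0:
        raise InvalidParameterError(f"activity must be >= 0, got {activity}")
    return SpecificActivity(value=activity / p_mass, activity=activity, p_mass=p_mass)
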