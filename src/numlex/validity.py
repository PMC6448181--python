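"""Domain validity rules: calendar month/day checks and age plausibility.

Clinical notes state dates like "June 31" without a year, so date validity
must be decidable from the (month, day) pair alone.  February 29 is
therefore governed by an explicit policy instead of a year lookup: the
default ``LENIENT_FEB29`` treats it as valid (some year makes it so), while
``STRICT_FEB29`` rejects it (most years do not).

Age plausibility uses a single configurable upper bound.  The default of
122 years is the longest documented human lifespan; any stated age above
it is treated as a data-quality error rather than a fact about the patient.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = [
    "LeapPolicy",
    "CalendarDate",
    "MONTH_NAMES",
    "MONTH_NUMBER",
    "MAX_PLAUSIBLE_AGE",
    "days_in_month",
    "is_valid_date",
    "is_plausible_age",
]

MONTH_NAMES: tuple[str, ...] = (
    "january", "february", "march", "april", "may", "june",
    "july", "august", "september", "october", "november", "december",
)

MONTH_NUMBER: dict[str, int] = {name: i + 1 for i, name in enumerate(MONTH_NAMES)}

#: Longest documented human lifespan, in years; ages above this are implausible.
MAX_PLAUSIBLE_AGE: int = 122

_MONTH_DAYS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


class LeapPolicy(str, Enum):
    """How to judge February 29 when no year is available."""

    LENIENT_FEB29 = "lenient_feb29"
    STRICT_FEB29 = "strict_feb29"


@dataclass(frozen=True)
class CalendarDate:
    """A year-less month/day pair as it appears in note text ("June 31")."""

    month: int
    day: int
    leap_policy: LeapPolicy = LeapPolicy.LENIENT_FEB29

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be 1-12, got {self.month}")
        if self.day < 1:
            raise ValueError(f"day must be >= 1, got {self.day}")


def days_in_month(month: int, leap_policy: LeapPolicy = LeapPolicy.LENIENT_FEB29) -> int:
    """Length of ``month`` under the given February-29 policy."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be 1-12, got {month}")
    if month == 2 and leap_policy is LeapPolicy.LENIENT_FEB29:
        return 29
    return _MONTH_DAYS[month - 1]


def is_valid_date(date: CalendarDate) -> bool:
    """True iff the day exists in the month ("January 31" yes, "June 31" no)."""
    return date.day <= days_in_month(date.month, date.leap_policy)


def is_plausible_age(age: int, bound: int = MAX_PLAUSIBLE_AGE) -> bool:
    """True iff ``age`` (in years) does not exceed the plausibility bound."""
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    return age <= bound
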