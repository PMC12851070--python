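"""Small shared helpers: rounding, ages, calendar-month arithmetic."""

from __future__ import annotations

import math
from datetime import date


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going away from zero-ward halves up.

    Python's builtin ``round`` uses banker's rounding; printed claims tables
    round halves up, so 0.5 -> 1, 1.5 -> 2.
    """
    return int(math.floor(x + 0.5))


def percent(count: int, total: int) -> int:
    """Integer percentage of ``count`` out of ``total``, half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total)


def age_at(birth_date: date, reference: date) -> int:
    """Completed years of age at ``reference``."""
    years = reference.year - birth_date.year
    if (reference.month, reference.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def month_index(d: date) -> int:
    """Months since year 0; consecutive calendar months differ by 1."""
    return d.year * 12 + (d.month - 1)


def month_bounds(index: int) -> tuple[date, date]:
    """First and last day of the calendar month with the given month index."""
    year, month = divmod(index, 12)
    month += 1
    if month == 12:
        last = date(year, 12, 31)
    else:
        from datetime import timedelta

        last = date(year, month + 1, 1) - timedelta(days=1)
    return date(year, month, 1), last
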