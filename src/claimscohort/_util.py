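"""Small shared helpers: rounding and date arithmetic conventions."""

from __future__ import annotations

import datetime as dt
from decimal import ROUND_HALF_UP, Decimal

DAYS_PER_YEAR = 365.25


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round to `ndigits` decimals, ties going away from zero.

    Python's built-in round() is banker's rounding; report tables here use
    the conventional half-away-from-zero rule (0.5 -> 1, -0.5 -> -1).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def parse_date(value) -> dt.date:
    """Parse an ISO-8601 date string (or pass a date through)."""
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value).strip())


def days_between(start: dt.date, end: dt.date) -> int:
    """Calendar-exact day count end - start."""
    return (end - start).days
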