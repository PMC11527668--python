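"""Partial-date handling for SRS tables.

Spontaneous-report dates come as bare digit strings — ``YYYYMMDD``,
``YYYYMM`` or ``YYYY`` — and are frequently absent.  Rather than discard or
impute partial dates, every parse returns both a calendar value (with a
first-of-period placeholder for partial dates) and an explicit precision
flag; downstream consumers decide what precision they require (e.g.
time-to-onset needs day precision on both ends).
"""

from __future__ import annotations

import datetime as _dt
from enum import Enum
from typing import Optional, Tuple


class DatePrecision(str, Enum):
    DAY = "day"
    MONTH = "month"
    YEAR = "year"
    MISSING = "missing"


ParsedDate = Tuple[Optional[_dt.date], DatePrecision]


def parse_date(raw: object) -> ParsedDate:
    """Parse a FAERS-style date string into ``(date, precision)``.

    Lenient by contract: anything unparseable (wrong length, month 13,
    February 30, non-digits) yields ``(None, MISSING)``.  Partial dates get a
    first-of-period placeholder so they remain sortable, with the precision
    flag recording what was actually known.
    """
    if raw is None:
        return None, DatePrecision.MISSING
    s = str(raw).strip()
    if s.endswith(".0"):  # numeric column read back through floats
        s = s[:-2]
    if not s or s.lower() in {"nan", "none"}:
        return None, DatePrecision.MISSING
    if not s.isdigit():
        return None, DatePrecision.MISSING
    try:
        if len(s) == 8:
            return _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8])), DatePrecision.DAY
        if len(s) == 6:
            return _dt.date(int(s[:4]), int(s[4:6]), 1), DatePrecision.MONTH
        if len(s) == 4:
            return _dt.date(int(s), 1, 1), DatePrecision.YEAR
    except ValueError:
        return None, DatePrecision.MISSING
    return None, DatePrecision.MISSING


def format_date(value: Optional[_dt.date], precision: DatePrecision) -> str:
    """Inverse of :func:`parse_date` for round-trip writing."""
    if value is None or precision == DatePrecision.MISSING:
        return ""
    if precision == DatePrecision.DAY:
        return f"{value.year:04d}{value.month:02d}{value.day:02d}"
    if precision == DatePrecision.MONTH:
        return f"{value.year:04d}{value.month:02d}"
    return f"{value.year:04d}"


def date_sort_key(raw: object) -> int:
    """Monotone integer key for ordering possibly-partial date strings.

    Day-precision dates order naturally; partial dates sort at the start of
    their period; missing/invalid dates sort before everything.
    """
    value, precision = parse_date(raw)
    if value is None:
        return -1
    return value.year * 10000 + value.month * 100 + value.day


def is_valid_or_empty(raw: object) -> bool:
    """True when ``raw`` is empty or parses to a real (possibly partial) date."""
    s = "" if raw is None else str(raw).strip()
    if not s or s.lower() in {"nan", "none"}:
        return True
    return parse_date(raw)[1] != DatePrecision.MISSING
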