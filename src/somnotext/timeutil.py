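"""Minute-resolution time arithmetic.

All timestamps in this package are naive local times held as integer
minutes since 2000-01-01T00:00 (the model is defined in minutes and clock
hours; no time-zone semantics are attached).  Helpers convert between
that representation, :class:`datetime.datetime`, and ISO-8601 strings.
"""

from __future__ import annotations

from datetime import datetime, timedelta

EPOCH = datetime(2000, 1, 1)
MIN_PER_DAY = 1440
MIN_PER_HOUR = 60

Minute = int  # type alias used in signatures throughout the package


def to_minutes(dt: datetime) -> int:
    """Convert a datetime to integer minutes since the package epoch.

    Seconds and microseconds are truncated (minute resolution).
    """
    delta = dt.replace(second=0, microsecond=0) - EPOCH
    return delta.days * MIN_PER_DAY + delta.seconds // 60


def from_minutes(m: float) -> datetime:
    """Convert minutes since the epoch back to a datetime (may carry seconds
    when ``m`` is fractional, e.g. a deprivation onset at a non-integer
    minute)."""
    return EPOCH + timedelta(minutes=float(m))


def parse_ts(s: str) -> int:
    """Parse an ISO-8601 timestamp string to minutes since the epoch.

    Raises ``ValueError`` for anything :func:`datetime.fromisoformat`
    rejects.  Sub-minute precision is truncated.
    """
    return to_minutes(datetime.fromisoformat(s.strip()))


def format_ts(m: float) -> str:
    """Render minutes-since-epoch as ISO-8601.

    Integer minutes render as ``YYYY-MM-DDTHH:MM``; fractional minutes
    include seconds so no information is hidden in audit exports.
    """
    dt = from_minutes(m)
    if dt.second == 0 and dt.microsecond == 0:
        return dt.strftime("%Y-%m-%dT%H:%M")
    return dt.replace(microsecond=0).strftime("%Y-%m-%dT%H:%M:%S")


def day_index(m: float) -> int:
    """Calendar-day index (days since epoch) of a timestamp."""
    return int(m) // MIN_PER_DAY


def hour_of(m: float) -> int:
    """Clock hour 0..23 of a timestamp."""
    return (int(m) % MIN_PER_DAY) // MIN_PER_HOUR
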