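"""Calendar-month arithmetic shared across the package.

Survey respondents state their age in whole years and months, so every
self-report computation works on calendar months and ignores day-of-month.
Months are represented internally as a single integer index
(``year * 12 + month - 1``) which makes interval arithmetic exact.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass


def month_index(year: int, month: int) -> int:
    """Map a (year, month) pair to a monotone integer month index."""
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range: {month}")
    return year * 12 + (month - 1)


def index_to_ym(index: int) -> tuple[int, int]:
    """Inverse of :func:`month_index`."""
    return index // 12, index % 12 + 1


def month_index_of(date: dt.date) -> int:
    return month_index(date.year, date.month)


def format_ym(index: int) -> str:
    y, m = index_to_ym(index)
    return f"{y:04d}-{m:02d}"


def parse_ym(text: str) -> int:
    """Parse a ``YYYY-MM`` string to a month index."""
    y, m = text.strip().split("-")
    return month_index(int(y), int(m))


@dataclass(frozen=True)
class MonthInterval:
    """Closed interval of calendar months, endpoints inclusive.

    ``start`` and ``end`` are month indices (see :func:`month_index`).
    Self-report proxy diagnosis windows are always exactly 12 months long;
    that stronger invariant is enforced where the window is built, not here.
    """

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"MonthInterval start {format_ym(self.start)} after end {format_ym(self.end)}"
            )

    @classmethod
    def from_strings(cls, start: str, end: str) -> "MonthInterval":
        return cls(parse_ym(start), parse_ym(end))

    @classmethod
    def from_dates(cls, start: dt.date, end: dt.date) -> "MonthInterval":
        return cls(month_index_of(start), month_index_of(end))

    @property
    def n_months(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "MonthInterval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def contains_date(self, date: dt.date) -> bool:
        return self.start <= month_index_of(date) <= self.end

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{format_ym(self.start)}..{format_ym(self.end)}"
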