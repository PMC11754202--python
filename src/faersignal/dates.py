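"""Partial calendar dates as they occur in spontaneous-report databases.

FAERS date fields are numeric strings of 4, 6 or 8 digits (``YYYY``,
``YYYYMM``, ``YYYYMMDD``).  Many reports carry only a year or a
year-month; imputing the missing components would silently sharpen the
data, so :class:`PartialDate` keeps an explicit precision tag instead.
Ordering comparisons (needed for deduplication) pad missing month/day
with 01 — the padding is used for sorting only and never leaks back
into the stored value.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True, slots=True)
class PartialDate:
    """A calendar date known to day, month or year precision."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("day precision requires a month")
        if not (1 <= self.year <= 9999):
            raise ValueError(f"year out of range: {self.year}")
        if self.month is not None and not (1 <= self.month <= 12):
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            # delegate day-of-month validity to the stdlib
            _dt.date(self.year, self.month, self.day)

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    @classmethod
    def parse(cls, text: str | None) -> Optional["PartialDate"]:
        """Parse a FAERS date string; ``None``/empty/garbage parse to None.

        Accepts 4, 6 or 8 digit forms, with or without ``-``/``/``
        separators.  A date that fails calendar validation (e.g. month
        13) is treated as unparseable rather than raising, because in
        the wild such values are data errors in a single row.
        """
        if text is None:
            return None
        digits = "".join(ch for ch in str(text).strip() if ch.isdigit())
        if len(digits) not in (4, 6, 8):
            return None
        try:
            year = int(digits[:4])
            month = int(digits[4:6]) if len(digits) >= 6 else None
            day = int(digits[6:8]) if len(digits) == 8 else None
            if month == 0:
                month, day = None, None
            if day == 0:
                day = None
            return cls(year, month, day)
        except ValueError:
            return None

    def sort_key(self) -> tuple[int, int, int]:
        """Ordering key padding missing month/day with 01 (sorting only)."""
        return (self.year, self.month or 1, self.day or 1)

    def to_date(self) -> _dt.date:
        if self.precision != "day":
            raise ValueError(f"date has {self.precision} precision, not day")
        return _dt.date(self.year, self.month, self.day)  # type: ignore[arg-type]

    def days_until(self, other: "PartialDate") -> Optional[int]:
        """Whole days from self to other; None unless both are day-precise."""
        if self.precision != "day" or other.precision != "day":
            return None
        return (other.to_date() - self.to_date()).days

    def faers_str(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.faers_str()
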