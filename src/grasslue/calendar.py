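"""The bimonthly calendar: six fixed two-month periods per year.

Period ``k`` (1-based) of a year covers calendar months ``2k-1`` and ``2k``,
so 2000–2022 yields 23 × 6 = 138 periods. Membership of a timestamp in a
period is tested against the half-open interval [start, end).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime

PERIODS_PER_YEAR = 6


@dataclass(frozen=True, order=True)
class Period:
    """One bimonthly period: (year, index 1..6) covering months 2k-1 and 2k."""

    year: int
    index: int

    def __post_init__(self):
        if not 1 <= self.index <= PERIODS_PER_YEAR:
            raise ValueError(f"period index must be 1..6, got {self.index}")

    @property
    def start(self) -> date:
        return date(self.year, 2 * self.index - 1, 1)

    @property
    def end(self) -> date:
        """Exclusive end: first day of the following period."""
        if self.index == PERIODS_PER_YEAR:
            return date(self.year + 1, 1, 1)
        return date(self.year, 2 * self.index + 1, 1)

    def contains(self, when) -> bool:
        d = when.date() if isinstance(when, datetime) else when
        return self.start <= d < self.end

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days

    def label(self) -> str:
        return f"{self.year}_p{self.index}"


@dataclass(frozen=True)
class BimonthlyCalendar:
    """Inclusive year range expanded to the ordered list of bimonthly periods."""

    start_year: int
    end_year: int

    def __post_init__(self):
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year")

    @property
    def periods(self) -> list[Period]:
        return [
            Period(y, k)
            for y in range(self.start_year, self.end_year + 1)
            for k in range(1, PERIODS_PER_YEAR + 1)
        ]

    def __len__(self) -> int:
        return (self.end_year - self.start_year + 1) * PERIODS_PER_YEAR

    def __iter__(self):
        return iter(self.periods)

    def period_of(self, when) -> Period:
        """The period containing a date/datetime (must fall in the year range)."""
        d = when.date() if isinstance(when, datetime) else when
        if not self.start_year <= d.year <= self.end_year:
            raise ValueError(f"{d} outside calendar years {self.start_year}-{self.end_year}")
        return Period(d.year, (d.month + 1) // 2)

    def year_periods(self, year: int) -> list[Period]:
        return [Period(year, k) for k in range(1, PERIODS_PER_YEAR + 1)]
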