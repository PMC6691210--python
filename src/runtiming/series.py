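"""Day-indexed series and stream-life schedules.

All timing arithmetic uses 1-based day-of-year (Jan 1 = day 1); a season
never wraps a year boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DailySeries:
    """A contiguous run of daily values (counts, discharge, °C) for one year.

    ``values[i]`` belongs to day-of-year ``first_day + i``.
    """

    year: int
    first_day: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not 1 <= self.first_day:
            raise ValueError("first_day must be >= 1")
        if self.last_day > 366:
            raise ValueError("series runs past the end of the year")

    @property
    def last_day(self) -> int:
        return self.first_day + len(self.values) - 1

    @property
    def days(self) -> np.ndarray:
        return np.arange(self.first_day, self.last_day + 1)

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def value_on(self, day: int) -> float:
        """Value on a day-of-year; 0 outside the stored window."""
        if day < self.first_day or day > self.last_day:
            return 0.0
        return float(self.values[day - self.first_day])

    def trimmed(self, eps: float = 0.0) -> "DailySeries":
        """Drop leading/trailing days with |value| <= eps."""
        nz = np.nonzero(np.abs(self.values) > eps)[0]
        if len(nz) == 0:
            return DailySeries(self.year, self.first_day, np.zeros(1))
        lo, hi = nz[0], nz[-1]
        return DailySeries(self.year, self.first_day + int(lo),
                           self.values[lo:hi + 1].copy())


@dataclass
class StreamLifeSchedule:
    """Days an adult survives in-river, by entry date and year.

    Within a year the span declines linearly from ``initial`` (earliest
    entrants) to ``final`` (latest); early-arriving salmon live longer.
    ``between_year_trend`` is the total additive change in both endpoints
    from the first to the last year of a dataset. Per-cohort spans are
    clamped at 1 day.

    ``anchor_start_day``/``anchor_end_day`` pin the within-year
    interpolation; when None they default to the extent of the live
    series being reconstructed.
    """

    initial: float
    final: float
    between_year_trend: float = 0.0
    anchor_start_day: int | None = None
    anchor_end_day: int | None = None

    def __post_init__(self) -> None:
        if self.final > self.initial:
            raise ValueError("final stream-life must not exceed initial")
        if self.initial < 1:
            raise ValueError("initial stream-life must be >= 1 day")

    @property
    def mean_stream_life(self) -> float:
        """Season-average span: midpoint of the initial and final values."""
        return 0.5 * (self.initial + self.final)

    def for_year(self, year: int, first_year: int,
                 last_year: int) -> "StreamLifeSchedule":
        """Schedule for one year under the between-year trend."""
        if last_year > first_year:
            frac = (year - first_year) / (last_year - first_year)
        else:
            frac = 0.0
        shift = self.between_year_trend * frac
        ini = max(1.0, self.initial + shift)
        fin = max(1.0, min(ini, self.final + shift))
        return StreamLifeSchedule(ini, fin, 0.0,
                                  self.anchor_start_day, self.anchor_end_day)

    def span_on(self, day: np.ndarray | float, anchor_start: int,
                anchor_end: int) -> np.ndarray:
        """Stream-life (float days) for entrants on ``day``."""
        if anchor_end <= anchor_start:
            frac = np.zeros_like(np.asarray(day, dtype=float))
        else:
            frac = np.clip((np.asarray(day, dtype=float) - anchor_start)
                           / (anchor_end - anchor_start), 0.0, 1.0)
        return np.maximum(1.0, self.initial + (self.final - self.initial) * frac)

    def death_offset(self, day: np.ndarray | float, anchor_start: int,
                     anchor_end: int) -> np.ndarray:
        """Integer days from entry to death (entrants on d are alive on
        days d .. d+offset-1 and die on d+offset)."""
        span = self.span_on(day, anchor_start, anchor_end)
        return np.maximum(1, np.rint(span)).astype(int)


@dataclass
class EntryDistribution:
    """Fitted normal river-entry distribution for one year."""

    year: int
    mu: float
    sigma: float
    fit_sse: float
    raw_entries: DailySeries | None = None
    spawn_delay: float = 0.0

    @property
    def mu_spawn(self) -> float:
        return self.mu + self.spawn_delay


@dataclass
class TimingSummary:
    """Percentile completion dates for one year and process."""

    year: int
    label: str
    dates: dict[int, float] = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.dates[90] - self.dates[10]
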