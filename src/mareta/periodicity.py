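"""Seasonal-pattern classification of abundance time series.

A per-MAG abundance series sampled over >= 2 years is classified into one
of four temporal categories by a peak-recurrence rule: a peak *recurs*
when another peak occurs 12 +/- 1 months later with height at least 25%
of the earlier peak. A series is COMPLETE_CYCLIC when every year-to-year
transition within its span carries a recurring peak, INCOMPLETE_CYCLIC
when some but not all do, TRANSIENT when there is exactly one peak, and
IRREGULAR otherwise (several peaks, none recurring). A year with no peak
counts as a failed transition, not a skipped one.

Peak detection (the rule itself does not define "peak") uses strict local
maxima — endpoints tested one-sided — with a floor of 10% of the series
maximum to suppress noise bumps. Dates are mapped to calendar month
indices (mid-month rounding), not 30-day bins.
"""

from __future__ import annotations

import calendar
import dataclasses
import datetime as _dt
import enum
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_MIN_HEIGHT_FRAC = 0.10
DEFAULT_MONTH_TOLERANCE = 1
DEFAULT_RECURRENCE_FRAC = 0.25

__all__ = [
    "PatternClass",
    "TimeSeries",
    "Peak",
    "month_index",
    "detect_peaks",
    "classify_pattern",
    "classify_series",
    "classify_table",
]


class PatternClass(enum.Enum):
    COMPLETE_CYCLIC = "complete_cyclic"
    INCOMPLETE_CYCLIC = "incomplete_cyclic"
    TRANSIENT = "transient"
    IRREGULAR = "irregular"


def month_index(date: _dt.date, origin: _dt.date | None = None) -> int:
    """Calendar month index of a date, rounded to the nearest month.

    A sample taken past mid-month rounds to the next month, so monthly
    cruises with drifting sampling days land on stable indices.
    """
    frac = (date.day - 1) / calendar.monthrange(date.year, date.month)[1]
    idx = date.year * 12 + (date.month - 1) + round(frac)
    if origin is not None:
        idx -= origin.year * 12 + (origin.month - 1)
    return idx


@dataclasses.dataclass(frozen=True)
class Peak:
    date: _dt.date
    height: float
    index: int  # position in the series
    month: int  # month index relative to series start


@dataclasses.dataclass(frozen=True)
class TimeSeries:
    dates: tuple[_dt.date, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.dates) != len(self.values):
            raise ValueError("dates and values differ in length")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("dates must be strictly increasing")
        if any(v < 0 for v in self.values):
            raise ValueError("abundances must be >= 0")

    @property
    def months(self) -> tuple[int, ...]:
        origin = self.dates[0]
        return tuple(month_index(d, origin) for d in self.dates)

    @property
    def span_months(self) -> int:
        return self.months[-1]


def detect_peaks(
    series: TimeSeries, min_height_frac: float = DEFAULT_MIN_HEIGHT_FRAC
) -> list[Peak]:
    """Strict local maxima above a fraction of the global maximum.

    Endpoints are eligible with a one-sided test. An all-zero series has
    no peaks.
    """
    if not 0 < min_height_frac < 1:
        raise ValueError("min_height_frac must be in (0, 1)")
    v = np.asarray(series.values, dtype=float)
    if len(v) == 0 or v.max() <= 0:
        return []
    floor = min_height_frac * v.max()
    months = series.months
    peaks = []
    for i, h in enumerate(v):
        if h <= 0 or h < floor:
            continue
        left_ok = i == 0 or v[i - 1] < h
        right_ok = i == len(v) - 1 or v[i + 1] < h
        if left_ok and right_ok:
            peaks.append(Peak(series.dates[i], float(h), i, months[i]))
    return peaks


def classify_pattern(
    peaks: Sequence[Peak],
    series: TimeSeries,
    month_tolerance: int = DEFAULT_MONTH_TOLERANCE,
    recurrence_frac: float = DEFAULT_RECURRENCE_FRAC,
) -> PatternClass:
    """Apply the peak-recurrence rule to detected peaks.

    A peak P recurs when some peak Q satisfies
    ``12 - tol <= month(Q) - month(P) <= 12 + tol`` and
    ``height(Q) >= recurrence_frac * height(P)``. Year-to-year transition
    t (t = 0 .. span//12 - 1) is covered when a peak dated within months
    [12t, 12(t+1)) recurs.
    """
    if len(peaks) == 0:
        return PatternClass.IRREGULAR
    if len(peaks) == 1:
        return PatternClass.TRANSIENT

    def recurs(p: Peak) -> bool:
        lo, hi = 12 - month_tolerance, 12 + month_tolerance
        return any(
            lo <= q.month - p.month <= hi and q.height >= recurrence_frac * p.height
            for q in peaks
        )

    n_transitions = series.span_months // 12
    if n_transitions == 0:
        return PatternClass.IRREGULAR
    covered = []
    for t in range(n_transitions):
        window = [p for p in peaks if 12 * t <= p.month < 12 * (t + 1)]
        covered.append(any(recurs(p) for p in window))
    if all(covered):
        return PatternClass.COMPLETE_CYCLIC
    if any(covered):
        return PatternClass.INCOMPLETE_CYCLIC
    return PatternClass.IRREGULAR


def classify_series(
    series: TimeSeries,
    min_height_frac: float = DEFAULT_MIN_HEIGHT_FRAC,
    month_tolerance: int = DEFAULT_MONTH_TOLERANCE,
    recurrence_frac: float = DEFAULT_RECURRENCE_FRAC,
) -> tuple[PatternClass, list[Peak]]:
    """Detect peaks then classify; returns (class, peaks)."""
    if len(series.values) < 4:
        raise ValueError("need at least 4 time points to classify")
    peaks = detect_peaks(series, min_height_frac=min_height_frac)
    return classify_pattern(peaks, series, month_tolerance, recurrence_frac), peaks


def classify_table(
    tidy: pd.DataFrame,
    min_height_frac: float = DEFAULT_MIN_HEIGHT_FRAC,
    month_tolerance: int = DEFAULT_MONTH_TOLERANCE,
    recurrence_frac: float = DEFAULT_RECURRENCE_FRAC,
) -> pd.DataFrame:
    """Classify every MAG in a tidy (mag_id, date, abundance) table."""
    rows = []
    for mag_id, grp in tidy.groupby("mag_id", sort=True):
        grp = grp.sort_values("date")
        series = TimeSeries(
            dates=tuple(
                d.date() if hasattr(d, "date") else _dt.date.fromisoformat(str(d))
                for d in grp["date"]
            ),
            values=tuple(float(x) for x in grp["abundance"]),
        )
        cls, peaks = classify_series(
            series, min_height_frac, month_tolerance, recurrence_frac
        )
        rows.append(
            {
                "mag_id": mag_id,
                "pattern": cls.value,
                "n_peaks": len(peaks),
                "span_months": series.span_months,
            }
        )
    return pd.DataFrame(rows)
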