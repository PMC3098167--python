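"""User-facing trend requests and cross-source comparison statistics.

A trend request asks for up to five distinct query patterns over the five
years (260 weeks) ending the week before the request, optionally with a
weekly media-article-count overlay. Each pattern's weekly counts are
normalized by the expected-volume trend before presentation. Comparison
helpers rescale series to the external 0–100 dialect, locate peak weeks,
and measure lead/lag by lagged Pearson correlation.

Sign convention for :func:`lead_lag`: a *negative* best lag means the
first series leads the second (its excursions happen earlier).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .logs import QueryLogEntry
from .normalize import TrendModel, normalize
from .patterns import QueryPattern
from .weeks import (ValueKind, WeekConvention, WeekId, WeeklySeries, aggregate,
                    week_range)

__all__ = [
    "WINDOW_WEEKS",
    "MAX_PATTERNS",
    "LogStore",
    "TrendRequest",
    "TrendResult",
    "build_window",
    "run_request",
    "read_media_counts",
    "rescale_0_100",
    "peak_week",
    "lead_lag",
    "LeadLagResult",
]

#: "Five years" of weeks: 5 × 52, constant across 53-week ISO years.
WINDOW_WEEKS = 260
MAX_PATTERNS = 5


@dataclass
class LogStore:
    """Entries plus the declared missing-log date ranges."""

    entries: Sequence[QueryLogEntry]
    gaps: Sequence[tuple[date, date]] = ()


@dataclass(frozen=True)
class TrendRequest:
    """1–5 mutually distinct patterns, anchored at the request week."""

    patterns: tuple[QueryPattern, ...]
    request_week: WeekId
    include_media: bool = False
    media_topic: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.patterns) <= MAX_PATTERNS:
            raise ValidationError(
                f"a request takes 1–{MAX_PATTERNS} patterns, got {len(self.patterns)}")
        canon = [p.canonical for p in self.patterns]
        if len(set(canon)) != len(canon):
            raise ValidationError(f"patterns must be unique, got {canon}")
        if self.request_week.convention is not WeekConvention.MONDAY_START:
            raise ValidationError("requests use Monday-start (ISO) weeks")


@dataclass
class TrendResult:
    """Normalized series per pattern over a shared window, media optional."""

    window: tuple[WeekId, WeekId]
    series: list[WeeklySeries]
    media: WeeklySeries | None = None
    anniversary_weeks: list[WeekId] = field(default_factory=list)


def build_window(request_week: WeekId) -> tuple[WeekId, WeekId]:
    """The 260-week reporting window ending the week before the request."""
    last = request_week + (-1)
    first = last + (-(WINDOW_WEEKS - 1))
    return first, last


def _anniversary_weeks(first: WeekId, last: WeekId) -> list[WeekId]:
    """The week carrying the window-end week number, once per year."""
    marks = []
    for year in range(first.iso_year, last.iso_year + 1):
        try:
            mark = WeekId(year, last.week, last.convention)
        except ValidationError:  # week 53 does not exist in every year
            continue
        if first <= mark <= last:
            marks.append(mark)
    return marks


def run_request(request: TrendRequest, store: LogStore, trend: TrendModel,
                media: WeeklySeries | None = None) -> TrendResult:
    """Aggregate and normalize each requested pattern over the window."""
    window = build_window(request.request_week)
    uncovered = trend.covers(week_range(*window))
    if uncovered:
        raise ValidationError(
            f"trend does not cover the request window (first uncovered: {uncovered[0]})")
    series = []
    for pattern in request.patterns:
        counts = aggregate(store.entries, pattern, WeekConvention.MONDAY_START,
                           gaps=store.gaps, span=window)
        series.append(normalize(counts, trend))
    media_out = None
    if request.include_media:
        if media is None:
            raise ValidationError("request asks for media overlay but no media series given")
        media_out = media.restrict(*window)
    return TrendResult(window=window, series=series, media=media_out,
                       anniversary_weeks=_anniversary_weeks(*window))


def read_media_counts(source: str | Path, topic: str | None = None) -> WeeklySeries:
    """Read a weekly media-article-count CSV: ``iso_year,week,count``."""
    path = Path(source)
    points: dict[WeekId, float] = {}
    with open(path, encoding="utf-8", newline="") as handle:
        for row_number, row in enumerate(csv.reader(
                line for line in handle if not line.startswith("#")), start=1):
            if not row:
                continue
            if row_number == 1 and not row[0].strip().lstrip("-").isdigit():
                continue  # header row
            try:
                year, week, count = int(row[0]), int(row[1]), int(row[2])
            except (ValueError, IndexError):
                raise ValidationError(f"{path.name} row {row_number}: malformed media row {row!r}") from None
            if count < 0:
                raise ValidationError(f"{path.name} row {row_number}: negative article count {count}")
            points[WeekId(year, week)] = float(count)
    return WeeklySeries.from_mapping(topic or path.stem, points, ValueKind.RAW_COUNT)


def rescale_0_100(series: WeeklySeries) -> WeeklySeries:
    """Rescale to the external relative-volume dialect: max maps to 100."""
    observed = series.values[~series.missing_mask]
    if observed.size == 0:
        raise ValidationError("cannot rescale an all-missing series")
    if np.any(observed < 0):
        raise ValidationError("rescale requires non-negative values")
    peak = observed.max()
    if peak <= 0:
        raise ValidationError("cannot rescale an all-zero series")
    return series.with_values(np.minimum(series.values * (100.0 / peak), 100.0),
                              ValueKind.SCALED_0_100)


def peak_week(series: WeeklySeries) -> WeekId:
    """Week of the maximum value; ties go to the earliest week."""
    best_week, best_value = None, -math.inf
    for week, value in series:
        if not math.isnan(value) and value > best_value:
            best_week, best_value = week, value
    if best_week is None:
        raise ValidationError("series has no observed values")
    return best_week


@dataclass(frozen=True)
class LeadLagResult:
    best_lag: int
    correlation_at_best: float
    correlations: dict[int, float]


def lead_lag(series_a: WeeklySeries, series_b: WeeklySeries, max_lag: int) -> LeadLagResult:
    """Lagged Pearson correlation between two aligned weekly series.

    At lag *k* the pairs are (a at week w+k, b at week w); the returned
    ``best_lag`` maximizes the correlation, ties broken toward smaller
    ``|lag|`` then toward the negative lag. ``best_lag < 0`` means
    ``series_a`` leads ``series_b``. Every tested lag must have at least
    10 observed pairs.
    """
    if series_a.convention is not series_b.convention:
        raise ValidationError("lead_lag requires series in the same week convention")
    if max_lag < 0:
        raise ValidationError("max_lag must be non-negative")
    a = dict(zip(series_a.weeks, series_a.values))
    correlations: dict[int, float] = {}
    for lag in range(-max_lag, max_lag + 1):
        xs, ys = [], []
        for week, b_value in series_b:
            if math.isnan(b_value):
                continue
            a_value = a.get(week + lag, math.nan)
            if math.isnan(a_value):
                continue
            xs.append(a_value)
            ys.append(b_value)
        if len(xs) < 10:
            raise InsufficientDataError(
                f"only {len(xs)} overlapping observed pairs at lag {lag} (need ≥ 10)")
        x_arr, y_arr = np.asarray(xs), np.asarray(ys)
        if x_arr.std() == 0 or y_arr.std() == 0:
            correlations[lag] = 0.0
        else:
            correlations[lag] = float(np.corrcoef(x_arr, y_arr)[0, 1])
    best = max(correlations, key=lambda k: (correlations[k], -abs(k), -k))
    return LeadLagResult(best_lag=best, correlation_at_best=correlations[best],
                         correlations=correlations)
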