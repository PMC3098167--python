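"""Calendar logic and weekly aggregation.

Two week dialects coexist in surveillance data: strict ISO-8601 weeks
(Monday start, week 1 contains the year's first Thursday — the Swedish
convention) and Sunday-start weeks as used by external relative-volume
feeds. A Sunday-start week is labeled by the ISO week of the Monday it
contains, which makes the cross-dialect mapping deterministic and
invertible: Sunday-start week (y, w) starts one day before ISO week
(y, w).

Weekly series distinguish a week with zero matching queries (an observed
0) from a week whose logs are missing (a gap): gaps are declared as date
ranges and stored as NaN, never inferred from zeros.
"""

from __future__ import annotations

import csv
import enum
import functools
import math
import re
from collections import Counter
from dataclasses import dataclass
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyOverlapError, ValidationError
from .logs import QueryLogEntry
from .patterns import QueryPattern

__all__ = [
    "WeekConvention",
    "WeekId",
    "ValueKind",
    "WeeklySeries",
    "assign_week",
    "aggregate",
    "total_volume",
    "align",
]


class WeekConvention(str, enum.Enum):
    MONDAY_START = "monday_start"
    SUNDAY_START = "sunday_start"


class ValueKind(str, enum.Enum):
    RAW_COUNT = "raw_count"
    NORMALIZED = "normalized"
    SCALED_0_100 = "scaled_0_100"


# date.toordinal() of 0001-01-01 (a Monday) is 1, so Monday ordinals are
# ≡ 1 (mod 7) and Sunday ordinals ≡ 0 (mod 7).
_MONDAY_OFFSET = 1


@functools.total_ordering
@dataclass(frozen=True, slots=True)
class WeekId:
    """A week label: ISO year, week number, and week-start convention."""

    iso_year: int
    week: int
    convention: WeekConvention = WeekConvention.MONDAY_START

    def __post_init__(self) -> None:
        object.__setattr__(self, "convention", WeekConvention(self.convention))
        try:
            date.fromisocalendar(self.iso_year, self.week, 1)
        except ValueError as exc:
            raise ValidationError(f"invalid week ({self.iso_year}, {self.week}): {exc}") from None

    # -- calendar anchors -------------------------------------------------
    @property
    def monday(self) -> date:
        """The Monday whose ISO week carries this label."""
        return date.fromisocalendar(self.iso_year, self.week, 1)

    @property
    def start(self) -> date:
        """First day of the week under this convention."""
        if self.convention is WeekConvention.SUNDAY_START:
            return self.monday - timedelta(days=1)
        return self.monday

    @property
    def end(self) -> date:
        return self.start + timedelta(days=6)

    @classmethod
    def from_date(cls, when: date | datetime, convention: WeekConvention = WeekConvention.MONDAY_START) -> "WeekId":
        if isinstance(when, datetime):
            when = when.date()
        convention = WeekConvention(convention)
        if convention is WeekConvention.SUNDAY_START:
            # Sunday-start period containing `when`; labeled by its Monday.
            when = when + timedelta(days=1)
        y, w, _ = when.isocalendar()
        return cls(y, w, convention)

    @classmethod
    def parse(cls, text: str, convention: WeekConvention = WeekConvention.MONDAY_START) -> "WeekId":
        """Parse ``2010-W35`` / ``2010W35`` / ``2010-35``."""
        m = re.fullmatch(r"(\d{4})-?W?(\d{1,2})", text.strip())
        if not m:
            raise ValidationError(f"cannot parse week label {text!r} (expected e.g. 2010-W35)")
        return cls(int(m.group(1)), int(m.group(2)), convention)

    # -- ordering and arithmetic ------------------------------------------
    def _check_convention(self, other: "WeekId") -> None:
        if self.convention is not other.convention:
            raise ValidationError(
                f"cannot compare weeks across conventions ({self.convention.value} vs {other.convention.value})"
            )

    def __lt__(self, other: "WeekId") -> bool:
        self._check_convention(other)
        return self.start < other.start

    def __add__(self, weeks: int) -> "WeekId":
        return WeekId.from_date(self.start + timedelta(weeks=weeks), self.convention)

    def __sub__(self, other):
        if isinstance(other, WeekId):
            self._check_convention(other)
            return (self.start - other.start).days // 7
        return self + (-other)

    def to_monday_start(self) -> "WeekId":
        """Re-key to the Monday-start dialect (label is preserved)."""
        return WeekId(self.iso_year, self.week, WeekConvention.MONDAY_START)

    def __str__(self) -> str:
        return f"{self.iso_year}-W{self.week:02d}"


def assign_week(timestamp: datetime | date, convention: WeekConvention = WeekConvention.MONDAY_START) -> WeekId:
    """Week containing the timestamp; a week-start day opens the new week."""
    return WeekId.from_date(timestamp, convention)


def week_range(first: WeekId, last: WeekId) -> list[WeekId]:
    """All weeks from ``first`` to ``last`` inclusive."""
    if last < first:
        raise ValidationError(f"week range end {last} precedes start {first}")
    return [first + k for k in range(last - first + 1)]


class WeeklySeries:
    """Values keyed by strictly increasing weeks of one convention.

    Missing weeks are NaN. Raw counts must be non-negative integers;
    scaled values must lie in [0, 100].
    """

    def __init__(self, label: str, weeks: Sequence[WeekId], values: Sequence[float],
                 value_kind: ValueKind = ValueKind.RAW_COUNT):
        self.label = label
        self.value_kind = ValueKind(value_kind)
        self.weeks: tuple[WeekId, ...] = tuple(weeks)
        self.values = np.asarray(values, dtype=float)
        if len(self.weeks) != len(self.values):
            raise ValidationError("weeks and values differ in length")
        if self.weeks:
            conventions = {w.convention for w in self.weeks}
            if len(conventions) > 1:
                raise ValidationError("all weeks in a series must share one convention")
            for a, b in zip(self.weeks, self.weeks[1:]):
                if not a < b:
                    raise ValidationError(f"weeks not strictly increasing at {a} -> {b}")
        observed = self.values[~np.isnan(self.values)]
        if self.value_kind is ValueKind.RAW_COUNT:
            if np.any(observed < 0) or np.any(observed != np.round(observed)):
                raise ValidationError("raw_count values must be non-negative integers")
        elif self.value_kind is ValueKind.SCALED_0_100:
            if observed.size and (observed.min() < 0 or observed.max() > 100):
                raise ValidationError("scaled values must lie in [0, 100]")

    # -- basics ------------------------------------------------------------
    @property
    def convention(self) -> WeekConvention:
        if not self.weeks:
            raise ValidationError("empty series has no convention")
        return self.weeks[0].convention

    def __len__(self) -> int:
        return len(self.weeks)

    def __iter__(self) -> Iterator[tuple[WeekId, float]]:
        return zip(self.weeks, self.values)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_observed(self) -> int:
        return int((~self.missing_mask).sum())

    def get(self, week: WeekId) -> float:
        """Value at a week; NaN if the week is missing or absent."""
        try:
            return float(self.values[self.weeks.index(week)])
        except ValueError:
            return math.nan

    @property
    def first_week(self) -> WeekId:
        return self.weeks[0]

    @property
    def last_week(self) -> WeekId:
        return self.weeks[-1]

    def with_values(self, values: Sequence[float], value_kind: ValueKind | None = None,
                    label: str | None = None) -> "WeeklySeries":
        return WeeklySeries(label if label is not None else self.label, self.weeks, values,
                            value_kind if value_kind is not None else self.value_kind)

    def restrict(self, first: WeekId, last: WeekId) -> "WeeklySeries":
        keep = [(w, v) for w, v in self if first <= w <= last]
        return WeeklySeries(self.label, [w for w, _ in keep], [v for _, v in keep], self.value_kind)

    @classmethod
    def from_mapping(cls, label: str, points: dict[WeekId, float],
                     value_kind: ValueKind = ValueKind.RAW_COUNT) -> "WeeklySeries":
        weeks = sorted(points)
        return cls(label, weeks, [points[w] for w in weeks], value_kind)

    # -- pandas / CSV ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iso_year": [w.iso_year for w in self.weeks],
            "week": [w.week for w in self.weeks],
            "value": self.values,
        })

    def to_csv(self, path: str | Path) -> Path:
        """CSV with metadata in ``#`` header comments; empty cell = missing."""
        path = Path(path)
        with open(path, "w", encoding="utf-8", newline="") as handle:
            handle.write(f"# label={self.label}\n")
            handle.write(f"# convention={self.convention.value if self.weeks else WeekConvention.MONDAY_START.value}\n")
            handle.write(f"# value_kind={self.value_kind.value}\n")
            writer = csv.writer(handle)
            writer.writerow(["iso_year", "week", "value"])
            for week, value in self:
                if math.isnan(value):
                    cell = ""
                elif self.value_kind is ValueKind.RAW_COUNT:
                    cell = str(int(value))
                else:
                    cell = repr(float(value))
                writer.writerow([week.iso_year, week.week, cell])
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "WeeklySeries":
        path = Path(path)
        meta = {"label": path.stem, "convention": WeekConvention.MONDAY_START.value,
                "value_kind": ValueKind.RAW_COUNT.value}
        rows: list[list[str]] = []
        with open(path, encoding="utf-8", newline="") as handle:
            for line in handle:
                if line.startswith("#"):
                    key, _, value = line[1:].strip().partition("=")
                    if value:
                        meta[key.strip()] = value.strip()
                    continue
                rows.extend(csv.reader([line]))
        if rows and rows[0][:2] == ["iso_year", "week"]:
            rows = rows[1:]
        convention = WeekConvention(meta["convention"])
        weeks, values = [], []
        for row in rows:
            if not row:
                continue
            weeks.append(WeekId(int(row[0]), int(row[1]), convention))
            values.append(float(row[2]) if len(row) > 2 and row[2] != "" else math.nan)
        return cls(meta["label"], weeks, values, ValueKind(meta["value_kind"]))


# -- aggregation -----------------------------------------------------------

def _gap_weeks(gaps: Sequence[tuple[date, date]], convention: WeekConvention) -> set[WeekId]:
    """Weeks any of whose days fall inside a declared missing-log range."""
    out: set[WeekId] = set()
    for start, stop in gaps:
        if stop < start:
            raise ValidationError(f"gap range {start}..{stop} is reversed")
        day = start
        while day <= stop:
            out.add(WeekId.from_date(day, convention))
            day += timedelta(days=7)
        out.add(WeekId.from_date(stop, convention))
    return out


def aggregate(entries: Sequence[QueryLogEntry], pattern: QueryPattern,
              convention: WeekConvention = WeekConvention.MONDAY_START,
              gaps: Sequence[tuple[date, date]] = (),
              span: tuple[WeekId, WeekId] | None = None) -> WeeklySeries:
    """Weekly counts of entries matching the pattern.

    The series covers every week of the span (default: first to last week
    observed over *all* entries, matching or not) with explicit zeros;
    weeks intersecting a declared gap are NaN. Counting is bucket-based on
    day ordinals, so entries need not be time-sorted.
    """
    convention = WeekConvention(convention)
    offset = 0 if convention is WeekConvention.SUNDAY_START else _MONDAY_OFFSET
    counts: Counter[int] = Counter()
    lo = hi = None
    from .patterns import _compiled  # compiled once, reused per entry

    regex = None if pattern.is_match_all else _compiled(pattern)
    for entry in entries:
        bucket = (entry.timestamp.date().toordinal() - offset) // 7
        if lo is None or bucket < lo:
            lo = bucket
        if hi is None or bucket > hi:
            hi = bucket
        if regex is None or regex.search(entry.query_text.casefold()):
            counts[bucket] += 1

    if span is not None:
        first, last = span
        if first.convention is not convention or last.convention is not convention:
            raise ValidationError("span convention does not match requested convention")
        lo, hi = (first.start.toordinal() - offset) // 7, (last.start.toordinal() - offset) // 7
    if lo is None:
        return WeeklySeries(pattern.canonical, [], [], ValueKind.RAW_COUNT)

    missing = _gap_weeks(gaps, convention)
    weeks, values = [], []
    for bucket in range(lo, hi + 1):
        week = WeekId.from_date(date.fromordinal(bucket * 7 + offset), convention)
        weeks.append(week)
        values.append(math.nan if week in missing else float(counts.get(bucket, 0)))
    return WeeklySeries(pattern.canonical, weeks, values, ValueKind.RAW_COUNT)


def total_volume(entries: Sequence[QueryLogEntry],
                 convention: WeekConvention = WeekConvention.MONDAY_START,
                 gaps: Sequence[tuple[date, date]] = (),
                 span: tuple[WeekId, WeekId] | None = None) -> WeeklySeries:
    """Total queries per week — aggregation with the match-all pattern."""
    series = aggregate(entries, QueryPattern.match_all(), convention, gaps, span)
    series.label = "total"
    return series


def align(series_list: Sequence[WeeklySeries]) -> pd.DataFrame:
    """Join series on weeks, re-keying Sunday-start series to Monday-start.

    Sunday-start weeks keep their label (the ISO week of the Monday they
    contain), so re-keying is a pure relabeling: no point is lost,
    duplicated, or invented. Output is restricted to the intersection of
    the spans; an empty intersection raises :class:`EmptyOverlapError`.
    """
    if not series_list:
        raise ValidationError("align requires at least one series")
    rekeyed = []
    for series in series_list:
        if not series.weeks:
            raise EmptyOverlapError(f"series {series.label!r} is empty")
        if series.convention is WeekConvention.SUNDAY_START:
            rekeyed.append(WeeklySeries(series.label, [w.to_monday_start() for w in series.weeks],
                                        series.values, series.value_kind))
        else:
            rekeyed.append(series)
    first = max(s.first_week for s in rekeyed)
    last = min(s.last_week for s in rekeyed)
    if last < first:
        raise EmptyOverlapError("series spans do not overlap")
    weeks = week_range(first, last)
    data = {}
    for series in rekeyed:
        lookup = dict(zip(series.weeks, series.values))
        data[series.label] = [lookup.get(w, math.nan) for w in weeks]
    frame = pd.DataFrame(data, index=pd.MultiIndex.from_tuples(
        [(w.iso_year, w.week) for w in weeks], names=["iso_year", "week"]))
    return frame
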