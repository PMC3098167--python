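"""Week calendars, weekly aggregation, and cross-dialect alignment."""

import math
from datetime import date, datetime, timedelta

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from querytrends import (
    EmptyOverlapError,
    QueryLogEntry,
    QueryPattern,
    ValidationError,
    ValueKind,
    WeekConvention,
    WeekId,
    WeeklySeries,
    aggregate,
    align,
    assign_week,
    count_matching,
    parse_pattern,
    total_volume,
)


class TestAssignWeek:
    def test_dataset_anchor_week(self):
        # 2005-07-04 is the Monday opening ISO week 27 of 2005.
        assert assign_week(datetime(2005, 7, 4, 0, 0)) == WeekId(2005, 27)

    def test_year_boundary(self):
        assert assign_week(date(2010, 1, 1)) == WeekId(2009, 53)
        assert assign_week(date(2010, 1, 4)) == WeekId(2010, 1)

    def test_sunday_start_boundary(self):
        # 2008-11-02 is a Sunday: it opens a new Sunday-start week, while
        # Monday-start assigns it to the previous week.
        sunday = date(2008, 11, 2)
        before = assign_week(sunday - timedelta(days=1), WeekConvention.SUNDAY_START)
        on = assign_week(sunday, WeekConvention.SUNDAY_START)
        after = assign_week(sunday + timedelta(days=1), WeekConvention.SUNDAY_START)
        assert on != before
        assert on == after
        assert assign_week(sunday) == assign_week(sunday - timedelta(days=1))

    def test_sunday_week_labeled_by_contained_monday(self):
        # Sunday 2008-11-02 starts the week containing Monday 2008-11-03,
        # which is ISO week 45.
        week = assign_week(date(2008, 11, 2), WeekConvention.SUNDAY_START)
        assert (week.iso_year, week.week) == (2008, 45)
        assert week.start == date(2008, 11, 2)

    @given(st.dates(min_value=date(2004, 1, 1), max_value=date(2012, 12, 31)),
           st.sampled_from(list(WeekConvention)))
    def test_total_deterministic_and_contiguous(self, day, convention):
        week = assign_week(day, convention)
        assert week.start <= day <= week.end
        next_week = assign_week(day + timedelta(days=1), convention)
        assert next_week in (week, week + 1)


class TestWeekIdArithmetic:
    def test_ordering_and_difference(self):
        a, b = WeekId(2009, 53), WeekId(2010, 1)  # 2009 has 53 ISO weeks
        assert a < b and b - a == 1 and a + 1 == b

    def test_cross_convention_comparison_rejected(self):
        with pytest.raises(ValidationError):
            WeekId(2009, 1) < WeekId(2009, 2, WeekConvention.SUNDAY_START)

    def test_invalid_week_number(self):
        with pytest.raises(ValidationError):
            WeekId(2010, 53)  # 2010 has 52 ISO weeks

    def test_parse(self):
        assert WeekId.parse("2010-W35") == WeekId(2010, 35)


def _entries(spec):
    return [QueryLogEntry(datetime.combine(day, datetime.min.time()), text)
            for day, text in spec]


class TestAggregate:
    def test_single_week_counts(self):
        day = date(2007, 3, 5)
        entries = _entries([(day, "kräkningar")] * 4 + [(day, "feber")] * 6)
        series = aggregate(entries, parse_pattern("kräkningar"))
        assert len(series) == 1
        assert series.values[0] == 4

    def test_zero_weeks_inside_span_are_explicit(self):
        entries = _entries([(date(2007, 3, 5), "feber"),
                            (date(2007, 3, 26), "feber")])
        series = aggregate(entries, parse_pattern("feber"))
        assert len(series) == 4
        assert list(series.values) == [1, 0, 0, 1]

    def test_conservation(self, small_scenario):
        from querytrends import generate_logs

        entries, truth = generate_logs(small_scenario)
        pattern = parse_pattern("*kräk*")
        series = aggregate(entries, pattern, gaps=small_scenario.gaps)
        assert np.nansum(series.values) == count_matching(pattern, entries)

    def test_five_week_gap_is_missing_not_zero(self, small_scenario):
        from querytrends import generate_logs

        entries, truth = generate_logs(small_scenario)
        series = total_volume(entries, gaps=small_scenario.gaps)
        gap_values = [series.get(w) for w in sorted(truth.gap_weeks)]
        assert len(gap_values) == 5
        assert all(math.isnan(v) for v in gap_values)
        assert not any(v == 0 for v in series.values[~series.missing_mask])

    def test_total_volume_equals_match_all_aggregate(self, small_scenario):
        from querytrends import generate_logs

        entries, _ = generate_logs(small_scenario)
        total = total_volume(entries)
        explicit = aggregate(entries, QueryPattern.match_all())
        assert list(total.values) == list(explicit.values)

    def test_total_volume_reproduces_generator_totals(self, default_world):
        series = total_volume(default_world.entries, gaps=default_world.scenario.gaps)
        realized = default_world.truth.realized["total"].to_numpy()
        for i, (week, value) in enumerate(series):
            if week in default_world.truth.gap_weeks:
                assert math.isnan(value)
            else:
                assert value == realized[i]

    def test_empty_entries_empty_series(self):
        series = total_volume([])
        assert len(series) == 0


class TestWeeklySeries:
    def test_raw_counts_must_be_nonnegative_integers(self):
        with pytest.raises(ValidationError):
            WeeklySeries("x", [WeekId(2007, 1)], [-1.0])
        with pytest.raises(ValidationError):
            WeeklySeries("x", [WeekId(2007, 1)], [1.5])

    def test_weeks_strictly_increasing(self):
        with pytest.raises(ValidationError):
            WeeklySeries("x", [WeekId(2007, 2), WeekId(2007, 1)], [1, 2])

    def test_csv_round_trip_preserves_missing(self, tmp_path):
        weeks = [WeekId(2007, 1) + k for k in range(4)]
        series = WeeklySeries("*kräk*", weeks, [1, math.nan, 0, 5])
        path = tmp_path / "series.csv"
        series.to_csv(path)
        again = WeeklySeries.from_csv(path)
        assert again.label == "*kräk*"
        assert again.value_kind is ValueKind.RAW_COUNT
        assert again.weeks == series.weeks
        assert np.array_equal(again.values, series.values, equal_nan=True)

    def test_csv_round_trip_normalized_exact(self, tmp_path):
        weeks = [WeekId(2007, 1) + k for k in range(3)]
        series = WeeklySeries("n", weeks, [0.1234567891234, 1.0, 2.5],
                              ValueKind.NORMALIZED)
        path = tmp_path / "series.csv"
        series.to_csv(path)
        assert list(WeeklySeries.from_csv(path).values) == list(series.values)


class TestAlign:
    def test_same_convention_join(self):
        weeks = [WeekId(2008, 1) + k for k in range(10)]
        a = WeeklySeries("a", weeks, range(10), ValueKind.NORMALIZED)
        b = WeeklySeries("b", weeks[2:], range(8), ValueKind.NORMALIZED)
        joined = align([a, b])
        assert len(joined) == 8
        assert list(joined["a"]) == list(range(2, 10))

    def test_cross_dialect_bijection_52_weeks(self):
        monday_weeks = [WeekId(2008, 1) + k for k in range(52)]
        sunday_weeks = [WeekId(w.iso_year, w.week, WeekConvention.SUNDAY_START)
                        for w in monday_weeks]
        a = WeeklySeries("monday", monday_weeks, np.arange(52.0), ValueKind.NORMALIZED)
        b = WeeklySeries("sunday", sunday_weeks, np.arange(52.0) + 100, ValueKind.NORMALIZED)
        # the dialects are shifted by one day on disk
        assert all(s.start == m.start - timedelta(days=1)
                   for s, m in zip(sunday_weeks, monday_weeks))
        joined = align([a, b])
        assert len(joined) == 52
        assert list(joined["sunday"]) == list(np.arange(52.0) + 100)
        assert list(joined["monday"]) == list(np.arange(52.0))

    def test_align_never_invents_values(self):
        weeks = [WeekId(2008, 1) + k for k in range(6)]
        a = WeeklySeries("a", weeks, [1, math.nan, 3, 4, math.nan, 6], ValueKind.NORMALIZED)
        joined = align([a])
        observed = joined["a"].dropna().to_numpy()
        assert sorted(observed) == [1, 3, 4, 6]

    def test_disjoint_spans_error(self):
        a = WeeklySeries("a", [WeekId(2007, 1)], [1.0], ValueKind.NORMALIZED)
        b = WeeklySeries("b", [WeekId(2009, 1)], [1.0], ValueKind.NORMALIZED)
        with pytest.raises(EmptyOverlapError):
            align([a, b])
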