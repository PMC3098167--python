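"""Trend requests, media overlays, and comparison statistics."""

import math

import numpy as np
import pytest

from querytrends import (
    InsufficientDataError,
    LogStore,
    TrendRequest,
    ValidationError,
    ValueKind,
    WeekConvention,
    WeekId,
    WeeklySeries,
    build_window,
    lead_lag,
    parse_pattern,
    peak_week,
    read_media_counts,
    rescale_0_100,
    run_request,
)
from querytrends.trends import WINDOW_WEEKS


class TestBuildWindow:
    def test_ends_week_before_request(self):
        first, last = build_window(WeekId(2010, 35))
        assert last == WeekId(2010, 34)
        assert last - first + 1 == WINDOW_WEEKS

    @pytest.mark.parametrize("request_week", [
        WeekId(2010, 35), WeekId(2010, 1), WeekId(2009, 53), WeekId(2012, 26),
    ])
    def test_length_is_260_weeks(self, request_week):
        first, last = build_window(request_week)
        assert last - first + 1 == 260
        assert last < request_week

    def test_request_in_week_one_ends_in_previous_iso_year(self):
        first, last = build_window(WeekId(2010, 1))
        assert last == WeekId(2009, 53)
        assert last.iso_year == 2009


class TestTrendRequest:
    def test_six_patterns_rejected(self):
        patterns = tuple(parse_pattern(t) for t in ["a", "b", "c", "d", "e", "f"])
        with pytest.raises(ValidationError):
            TrendRequest(patterns=patterns, request_week=WeekId(2010, 35))

    def test_duplicate_patterns_rejected(self):
        patterns = (parse_pattern("*kräk*"), parse_pattern(" *kräk* "))
        with pytest.raises(ValidationError):
            TrendRequest(patterns=patterns, request_week=WeekId(2010, 35))

    def test_run_request_full_window(self, default_pipeline):
        scenario = default_pipeline.scenario
        request_week = scenario.start_week + scenario.n_weeks  # week after span
        request = TrendRequest(
            patterns=(parse_pattern("*kräk*"), parse_pattern("diarre|diarré")),
            request_week=request_week)
        store = LogStore(default_pipeline.entries, gaps=scenario.gaps)
        result = run_request(request, store, default_pipeline.model)
        assert len(result.series) == 2
        first, last = result.window
        assert last == request_week + (-1)
        for series in result.series:
            assert series.first_week == first and series.last_week == last
            assert series.value_kind is ValueKind.NORMALIZED
        # one anniversary mark per year carrying the window-end week number
        assert all(w.week == last.week for w in result.anniversary_weeks)
        assert len(result.anniversary_weeks) >= 5

    def test_media_overlay_requires_series(self, default_pipeline):
        scenario = default_pipeline.scenario
        request = TrendRequest(patterns=(parse_pattern("*kräk*"),),
                               request_week=scenario.start_week + scenario.n_weeks,
                               include_media=True)
        store = LogStore(default_pipeline.entries, gaps=scenario.gaps)
        with pytest.raises(ValidationError):
            run_request(request, store, default_pipeline.model)

    def test_trend_must_cover_window(self, default_pipeline):
        request = TrendRequest(patterns=(parse_pattern("*kräk*"),),
                               request_week=WeekId(2020, 10))
        store = LogStore(default_pipeline.entries)
        with pytest.raises(ValidationError):
            run_request(request, store, default_pipeline.model)


class TestMediaCounts:
    def test_read_counts(self, tmp_path):
        path = tmp_path / "vinterkraksjuka.csv"
        path.write_text("iso_year,week,count\n" + "\n".join(
            f"2008,{w},{w % 7}" for w in range(1, 53)) + "\n")
        series = read_media_counts(path)
        assert len(series) == 52
        assert series.label == "vinterkraksjuka"
        assert series.value_kind is ValueKind.RAW_COUNT

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "media.csv"
        path.write_text("2008,1,5\n2008,2,-3\n")
        with pytest.raises(ValidationError, match="row 2"):
            read_media_counts(path)

    def test_malformed_row_names_row(self, tmp_path):
        path = tmp_path / "media.csv"
        path.write_text("2008,1,5\n2008,two,3\n")
        with pytest.raises(ValidationError, match="row 2"):
            read_media_counts(path)

    def test_round_trip_with_generator(self, tmp_path, small_scenario):
        from querytrends import generate_media_counts

        series = generate_media_counts(small_scenario, "kräk")
        path = tmp_path / "media.csv"
        series.to_csv(path)
        again = read_media_counts(path, topic="kräk")
        assert again.weeks == series.weeks
        assert list(again.values) == list(series.values)


class TestRescale:
    def test_arithmetic(self):
        series = _norm_series([2, 4, 8])
        assert list(rescale_0_100(series).values) == [25.0, 50.0, 100.0]

    def test_constant_series_all_100(self):
        assert list(rescale_0_100(_norm_series([3, 3, 3])).values) == [100.0] * 3

    def test_idempotent(self):
        once = rescale_0_100(_norm_series([2, 4, 8]))
        twice = rescale_0_100(once)
        assert list(once.values) == list(twice.values)
        assert twice.value_kind is ValueKind.SCALED_0_100

    def test_preserves_ranks(self):
        rng = np.random.default_rng(4)
        values = rng.random(30) * 50
        scaled = rescale_0_100(_norm_series(values))
        assert list(np.argsort(scaled.values)) == list(np.argsort(values))

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            rescale_0_100(_norm_series([0, 0, 0]))


def _norm_series(values, label="s", start=WeekId(2008, 1)):
    weeks = [start + k for k in range(len(values))]
    return WeeklySeries(label, weeks, values, ValueKind.NORMALIZED)


class TestPeakWeek:
    def test_single_point(self):
        assert peak_week(_norm_series([5.0])) == WeekId(2008, 1)

    def test_tie_breaks_to_earlier_week(self):
        assert peak_week(_norm_series([1, 7, 3, 7, 2])) == WeekId(2008, 2)

    def test_all_missing_rejected(self):
        with pytest.raises(ValidationError):
            peak_week(_norm_series([math.nan, math.nan]))

    def test_recovers_injected_peak(self, default_pipeline):
        from querytrends import aggregate, normalize

        scenario = default_pipeline.scenario
        counts = aggregate(default_pipeline.entries, parse_pattern("*kräk*"),
                           gaps=scenario.gaps)
        normalized = normalize(counts, default_pipeline.model)
        factor = default_pipeline.truth.epidemic_factor["kräk"]
        true_peak = default_pipeline.truth.weeks[int(np.argmax(factor))]
        assert abs(peak_week(normalized) - true_peak) <= 1


class TestLeadLag:
    def test_self_correlation(self):
        series = _norm_series(np.sin(np.arange(60) / 4) + 2)
        result = lead_lag(series, series, max_lag=4)
        assert result.best_lag == 0
        assert result.correlation_at_best == pytest.approx(1.0)

    @pytest.mark.parametrize("shift", [3, -2])
    def test_constructed_shift_recovered(self, shift):
        values = np.sin(np.arange(100) / 5) + np.cos(np.arange(100) / 11) + 3
        a = _norm_series(values)
        # b delayed by `shift` weeks: b(w) = a(w - shift)
        b_weeks = [WeekId(2008, 1) + k + shift for k in range(100)]
        b = WeeklySeries("b", b_weeks, values, ValueKind.NORMALIZED)
        result = lead_lag(a, b, max_lag=5)
        assert result.best_lag == -shift
        assert result.correlation_at_best == pytest.approx(1.0)

    def test_shift_consistency(self):
        """Shifting the second series by +k changes best_lag by -k."""
        rng = np.random.default_rng(8)
        values = rng.random(80) + np.sin(np.arange(80) / 6)
        a = _norm_series(values)
        lags = []
        for k in (0, 2):
            b = WeeklySeries("b", [WeekId(2008, 1) + i + k for i in range(80)],
                             values, ValueKind.NORMALIZED)
            lags.append(lead_lag(a, b, max_lag=4).best_lag)
        assert lags[1] - lags[0] == -2

    def test_cross_convention_rejected(self):
        a = _norm_series([1.0] * 20)
        weeks = [WeekId(2008, 1 + k, WeekConvention.SUNDAY_START) for k in range(20)]
        b = WeeklySeries("b", weeks, [1.0] * 20, ValueKind.NORMALIZED)
        with pytest.raises(ValidationError):
            lead_lag(a, b, max_lag=2)

    def test_insufficient_overlap(self):
        a = _norm_series([1.0, 2.0, 3.0])
        with pytest.raises(InsufficientDataError):
            lead_lag(a, a, max_lag=1)

    def test_white_noise_null(self):
        """Independent noise pairs rarely show strong best-lag correlation."""
        best = []
        weeks = [WeekId(2006, 1) + k for k in range(100)]
        for rep in range(1000):
            rng = np.random.default_rng(20_000 + rep)
            a = WeeklySeries("a", weeks, rng.standard_normal(100), ValueKind.NORMALIZED)
            b = WeeklySeries("b", weeks, rng.standard_normal(100), ValueKind.NORMALIZED)
            best.append(abs(lead_lag(a, b, max_lag=4).correlation_at_best))
        assert np.median(best) < 0.35
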