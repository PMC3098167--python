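"""Expected-volume trend fitting and normalization.

Raw weekly counts from a growing web site confound disease activity with
site usage: total volume both grows secularly and swells every winter, so
neither yearly nor same-week totals can serve as a denominator. Instead,
the expected search volume for each week is estimated from a *reference
query* — a common term with secular growth but no seasonality — by local
polynomial (LOESS-type) smoothing of its weekly counts, and every series
of interest is divided week-by-week by that expected value. The result
keeps seasonal and epidemic excursions while removing usage growth.

The smoother is a tricube-weighted local polynomial regression on the
week index; degree and neighborhood fraction are configuration, defaulted
wide enough (fraction 0.6, degree 2) that 52-week seasonality cannot leak
into the trend. Fitted values are floored at a small positive level so
normalization never divides by ~0 near span edges.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FitError, InsufficientDataError, ValidationError
from .weeks import ValueKind, WeekId, WeeklySeries, week_range

__all__ = [
    "DEFAULT_FRACTION",
    "DEFAULT_DEGREE",
    "TrendModel",
    "local_polynomial_smooth",
    "fit_trend",
    "normalize",
    "choose_reference_diagnostics",
    "ReferenceDiagnostics",
]

DEFAULT_FRACTION = 0.6
DEFAULT_DEGREE = 2
MIN_POINTS = 20


def local_polynomial_smooth(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray,
                            fraction: float = DEFAULT_FRACTION,
                            degree: int = DEFAULT_DEGREE) -> np.ndarray:
    """Tricube-weighted local polynomial regression (no robustness passes).

    At each evaluation point the nearest ``ceil(fraction * n)`` design
    points get tricube weights scaled by the neighborhood radius, a
    polynomial of the given degree is fitted by weighted least squares,
    and its value at the point is returned. With ``degree=1`` this is the
    classic non-robust LOWESS.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_eval = np.asarray(x_eval, dtype=float)
    n = x.size
    if n != y.size:
        raise ValidationError("x and y must have equal length")
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    if degree not in (1, 2):
        raise ValidationError(f"degree must be 1 or 2, got {degree}")
    k = max(degree + 2, int(math.ceil(fraction * n)))
    k = min(k, n)
    out = np.empty(x_eval.size)
    for i, x0 in enumerate(x_eval):
        dist = np.abs(x - x0)
        radius = np.partition(dist, k - 1)[k - 1]
        if radius <= 0:
            out[i] = y[dist == 0].mean()
            continue
        u = np.clip(dist / radius, 0.0, 1.0)
        w = (1 - u**3) ** 3
        use = w > 0
        t = x[use] - x0
        basis = np.vander(t, degree + 1, increasing=True)
        sw = np.sqrt(w[use])
        beta, *_ = np.linalg.lstsq(basis * sw[:, None], y[use] * sw, rcond=None)
        out[i] = beta[0]
    return out


@dataclass
class TrendModel:
    """Fitted expected-volume curve, evaluable at any week of its span."""

    reference_label: str
    weeks: tuple[WeekId, ...]
    expected_values: np.ndarray
    fraction: float = DEFAULT_FRACTION
    degree: int = DEFAULT_DEGREE
    _index: dict[WeekId, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.expected_values = np.asarray(self.expected_values, dtype=float)
        if len(self.weeks) != self.expected_values.size:
            raise ValidationError("weeks and expected values differ in length")
        if np.any(self.expected_values <= 0):
            raise ValidationError("expected volume must be strictly positive")
        self._index = {w: i for i, w in enumerate(self.weeks)}

    @property
    def first_week(self) -> WeekId:
        return self.weeks[0]

    @property
    def last_week(self) -> WeekId:
        return self.weeks[-1]

    def expected(self, week: WeekId) -> float:
        try:
            return float(self.expected_values[self._index[week]])
        except KeyError:
            raise ValidationError(f"week {week} outside fitted span "
                                  f"{self.first_week}..{self.last_week}") from None

    def covers(self, weeks: Sequence[WeekId]) -> list[WeekId]:
        """Weeks from the input that the model does NOT cover."""
        return [w for w in weeks if w not in self._index]

    def to_series(self) -> WeeklySeries:
        return WeeklySeries(f"expected[{self.reference_label}]", self.weeks,
                            self.expected_values, ValueKind.NORMALIZED)

    # -- persistence: CSV of (week, expected) + JSON sidecar of params ----
    def save(self, prefix: str | Path) -> tuple[Path, Path]:
        prefix = Path(prefix)
        csv_path = prefix.with_suffix(".csv")
        json_path = prefix.with_suffix(".json")
        self.to_series().to_csv(csv_path)
        json_path.write_text(json.dumps({
            "reference_label": self.reference_label,
            "fraction": self.fraction,
            "degree": self.degree,
        }, indent=2))
        return csv_path, json_path

    @classmethod
    def load(cls, prefix: str | Path) -> "TrendModel":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        series = WeeklySeries.from_csv(prefix.with_suffix(".csv"))
        return cls(meta["reference_label"], series.weeks, series.values,
                   fraction=meta["fraction"], degree=meta["degree"])


def fit_trend(reference_series: WeeklySeries,
              fraction: float = DEFAULT_FRACTION,
              degree: int = DEFAULT_DEGREE) -> TrendModel:
    """Fit the expected-volume trend to a reference query's weekly counts.

    Only observed weeks enter the fit; the smoother interpolates across
    gaps, so the model is evaluable at every week of the span including
    missing-log weeks. Fitted values are clipped below at half the
    smallest positive fitted value.
    """
    if reference_series.value_kind is not ValueKind.RAW_COUNT:
        raise ValidationError("trend is fitted on raw counts")
    weeks = tuple(week_range(reference_series.first_week, reference_series.last_week)) \
        if reference_series.weeks else ()
    if not weeks:
        raise FitError("reference series is empty")
    lookup = dict(zip(reference_series.weeks, reference_series.values))
    x_obs, y_obs = [], []
    for i, week in enumerate(weeks):
        value = lookup.get(week, math.nan)
        if not math.isnan(value):
            x_obs.append(i)
            y_obs.append(value)
    if len(x_obs) < MIN_POINTS:
        raise FitError(f"need at least {MIN_POINTS} observed weeks, got {len(x_obs)}")
    y_arr = np.asarray(y_obs, dtype=float)
    if not np.any(y_arr > 0):
        raise FitError("reference series is all zero — cannot normalize by it")
    fitted = local_polynomial_smooth(np.asarray(x_obs, dtype=float), y_arr,
                                     np.arange(len(weeks), dtype=float),
                                     fraction=fraction, degree=degree)
    positive = fitted[fitted > 0]
    if positive.size == 0:
        raise FitError("smoothed trend is nowhere positive")
    floor = 0.5 * positive.min()
    expected = np.maximum(fitted, floor)
    return TrendModel(reference_series.label, weeks, expected,
                      fraction=fraction, degree=degree)


def normalize(series: WeeklySeries, trend: TrendModel) -> WeeklySeries:
    """Divide weekly counts by the expected volume; missing stays missing."""
    if series.value_kind is not ValueKind.RAW_COUNT:
        raise ValidationError("normalize expects a raw_count series")
    uncovered = trend.covers(series.weeks)
    if uncovered:
        shown = ", ".join(str(w) for w in uncovered[:5])
        raise ValidationError(f"trend does not cover week(s) {shown}"
                              + ("…" if len(uncovered) > 5 else ""))
    values = [v / trend.expected(w) if not math.isnan(v) else math.nan
              for w, v in series]
    return WeeklySeries(series.label, series.weeks, values, ValueKind.NORMALIZED)


@dataclass(frozen=True)
class ReferenceDiagnostics:
    """Screening scores for a candidate reference query.

    ``seasonality_score`` is the adjusted fraction of detrended variance
    explained by week-of-year means (0 for white noise, →1 for a pure
    annual cycle); ``growth_score`` is the ratio of the fitted trend at
    span end to span start. A good reference shows low seasonality and
    whatever growth the site's usage exhibits.
    """

    seasonality_score: float
    growth_score: float


def choose_reference_diagnostics(candidate_series: WeeklySeries,
                                 fraction: float = DEFAULT_FRACTION,
                                 degree: int = DEFAULT_DEGREE) -> ReferenceDiagnostics:
    """Score a candidate reference query for seasonality and growth."""
    if candidate_series.n_observed < 104:
        raise InsufficientDataError(
            f"need ≥ 2 full years (104 observed weeks), got {candidate_series.n_observed}")
    trend = fit_trend(candidate_series, fraction=fraction, degree=degree)
    weeks, residuals, groups = [], [], []
    for week, value in candidate_series:
        if math.isnan(value):
            continue
        weeks.append(week)
        residuals.append(value - trend.expected(week))
        groups.append(week.week)
    resid = np.asarray(residuals)
    groups_arr = np.asarray(groups)
    n = resid.size
    overall = resid.mean()
    ss_total = float(((resid - overall) ** 2).sum())
    unique = np.unique(groups_arr)
    k = unique.size
    ss_within = 0.0
    for g in unique:
        sub = resid[groups_arr == g]
        ss_within += float(((sub - sub.mean()) ** 2).sum())
    if ss_total <= 0 or n <= k:
        seasonality = 0.0
    else:
        # Adjusted variance-explained: ~0 under white noise regardless of
        # the number of week-of-year groups.
        seasonality = max(0.0, 1.0 - (ss_within / (n - k)) / (ss_total / (n - 1)))
    growth = trend.expected(trend.last_week) / trend.expected(trend.first_week)
    return ReferenceDiagnostics(seasonality_score=float(seasonality), growth_score=float(growth))
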