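"""Synthetic query-log worlds with known ground truth.

The generator emulates the statistical structure of a medical web site's
search log over several years: secular growth of total usage (linear or
logistic), winter-high seasonal browsing volume, a growth-only reference
query, disease queries whose intensity is driven by injected epidemic
curves and by media-attention spikes, Poisson count noise, and
missing-log gaps. Disease labels emit a mix of the bare word, Swedish-style
compound fusions, and multi-word phrases, so star patterns and whole-token
patterns genuinely count different sets of queries.

Everything is deterministic under a fixed seed, and every generated
artifact comes with its ground truth (expected counts, realized counts,
epidemic factor curves), so downstream modules can be tested end-to-end
against what was actually injected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import date, datetime, time, timedelta
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .logs import QueryLogEntry
from .weeks import ValueKind, WeekConvention, WeekId, WeeklySeries

__all__ = [
    "GrowthSpec",
    "EpidemicEvent",
    "DiseaseQuery",
    "ReferenceQuery",
    "MediaEvent",
    "Scenario",
    "GroundTruth",
    "expected_weekly_counts",
    "generate_logs",
    "generate_media_counts",
    "generate_external_scaled",
    "default_scenario",
]

#: Day of year around which browsing volume peaks (mid-January winter).
_WINTER_PEAK_DOY = 15

#: Innocuous background queries; none contain a default disease stem or
#: the default reference term.
_BACKGROUND_LEXICON = (
    "huvudvärk", "feber", "ont i magen", "halsont", "klamydia",
    "graviditet", "allergi", "utslag", "hosta", "yrsel",
)


@dataclass(frozen=True)
class GrowthSpec:
    """Secular growth of expected total queries/week over the span."""

    shape: str = "logistic"  # "linear" or "logistic"
    start_level: float = 500.0
    end_level: float = 2500.0

    def curve(self, n_weeks: int) -> np.ndarray:
        t = np.arange(n_weeks, dtype=float)
        if n_weeks == 1:
            frac = np.zeros(1)
        elif self.shape == "linear":
            frac = t / (n_weeks - 1)
        elif self.shape == "logistic":
            u = 8.0 * (t / (n_weeks - 1) - 0.5)
            sig = 1.0 / (1.0 + np.exp(-u))
            lo, hi = 1.0 / (1.0 + math.exp(4.0)), 1.0 / (1.0 + math.exp(-4.0))
            frac = (sig - lo) / (hi - lo)
        else:
            raise ValidationError(f"unknown growth shape {self.shape!r}")
        return self.start_level + (self.end_level - self.start_level) * frac


@dataclass(frozen=True)
class EpidemicEvent:
    """A Gaussian-shaped multiplicative excursion of a disease query."""

    peak_week: WeekId
    width: float = 3.0   # weeks (Gaussian sigma)
    height: float = 6.0  # fold-increase over baseline at the peak

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValidationError(f"epidemic width must be ≥ 1 week, got {self.width}")
        if self.height <= 1:
            raise ValidationError(f"epidemic height must exceed 1, got {self.height}")


@dataclass(frozen=True)
class DiseaseQuery:
    """A disease topic and the query forms its sufferers actually type.

    ``token_form`` is the common full word (matched by a whole-token
    pattern); ``compound_forms`` are fused compounds that only a star
    pattern catches; ``phrase_forms`` are multi-word queries containing
    the token. ``token_epidemic_coupling`` < 1 damps the epidemic signal
    in the bare word, reflecting its background (curiosity) usage, so the
    star-pattern series is the epidemiologically sharper one.
    """

    label: str
    base_share: float
    epidemics: tuple[EpidemicEvent, ...] = ()
    token_form: str = ""
    compound_forms: tuple[str, ...] = ()
    phrase_forms: tuple[str, ...] = ()
    token_weight: float = 0.45
    compound_weight: float = 0.35
    phrase_weight: float = 0.20
    token_epidemic_coupling: float = 0.4

    def forms(self) -> list[tuple[str, float, float]]:
        """(query text, emission weight, epidemic coupling) per form."""
        out = [(self.token_form or self.label, self.token_weight, self.token_epidemic_coupling)]
        for group, weight in ((self.compound_forms, self.compound_weight),
                              (self.phrase_forms, self.phrase_weight)):
            for form in group:
                out.append((form, weight / len(group), 1.0))
        total = sum(w for _, w, _ in out)
        return [(f, w / total, c) for f, w, c in out]

    def token_matchable(self) -> set[str]:
        """Forms containing the bare token as a whole whitespace token."""
        token = (self.token_form or self.label).casefold()
        return {f for f, _, _ in self.forms() if token in f.casefold().split()}


@dataclass(frozen=True)
class ReferenceQuery:
    """Growth-only reference term: constant share of the growth curve."""

    label: str = "herpes"
    share: float = 0.04


@dataclass(frozen=True)
class MediaEvent:
    """A news-attention spike: articles/week decaying around a peak."""

    topic: str
    week: WeekId
    height: float = 40.0
    decay: float = 2.0  # e-folding time in weeks, two-sided

    def __post_init__(self) -> None:
        if self.height <= 0 or self.decay <= 0:
            raise ValidationError("media event height and decay must be positive")


@dataclass(frozen=True)
class Scenario:
    """Full parameterization of a synthetic query-log world."""

    start_week: WeekId = WeekId(2005, 27)
    n_weeks: int = 260
    growth: GrowthSpec = GrowthSpec()
    volume_seasonality: float = 0.25
    reference: ReferenceQuery = ReferenceQuery()
    diseases: tuple[DiseaseQuery, ...] = ()
    media_events: tuple[MediaEvent, ...] = ()
    media_effect: float = 0.5      # extra relative emission per 100 articles/week
    media_baseline: float = 2.0    # background articles/week per topic
    overdispersion: float | None = None  # negative-binomial excess if set
    gaps: tuple[tuple[date, date], ...] = ()
    seed: int = 2005

    def validate(self) -> None:
        if self.n_weeks < 1:
            raise ValidationError("scenario needs at least one week")
        if not 0 <= self.volume_seasonality < 1:
            raise ValidationError("volume_seasonality must lie in [0, 1)")
        if self.growth.start_level <= 0 or self.growth.end_level <= 0:
            raise ValidationError("growth levels must be positive")
        share_sum = self.reference.share + sum(d.base_share for d in self.diseases)
        if share_sum > 1:
            raise ValidationError(f"query shares sum to {share_sum:.3f} > 1")
        labels = [self.reference.label] + [d.label for d in self.diseases]
        if len(set(labels)) != len(labels):
            raise ValidationError("query labels must be unique")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValidationError("overdispersion, when set, must be positive")

    @property
    def weeks(self) -> list[WeekId]:
        return [self.start_week + k for k in range(self.n_weeks)]

    # -- YAML (de)serialization -------------------------------------------
    def to_dict(self) -> dict:
        return {
            "start_week": str(self.start_week),
            "n_weeks": self.n_weeks,
            "growth": {"shape": self.growth.shape,
                       "start_level": self.growth.start_level,
                       "end_level": self.growth.end_level},
            "volume_seasonality": self.volume_seasonality,
            "reference": {"label": self.reference.label, "share": self.reference.share},
            "diseases": [{
                "label": d.label, "base_share": d.base_share,
                "token_form": d.token_form,
                "compound_forms": list(d.compound_forms),
                "phrase_forms": list(d.phrase_forms),
                "token_weight": d.token_weight,
                "compound_weight": d.compound_weight,
                "phrase_weight": d.phrase_weight,
                "token_epidemic_coupling": d.token_epidemic_coupling,
                "epidemics": [{"peak_week": str(e.peak_week), "width": e.width,
                               "height": e.height} for e in d.epidemics],
            } for d in self.diseases],
            "media_events": [{"topic": m.topic, "week": str(m.week),
                              "height": m.height, "decay": m.decay}
                             for m in self.media_events],
            "media_effect": self.media_effect,
            "media_baseline": self.media_baseline,
            "overdispersion": self.overdispersion,
            "gaps": [[start.isoformat(), stop.isoformat()] for start, stop in self.gaps],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Scenario":
        return cls(
            start_week=WeekId.parse(data["start_week"]),
            n_weeks=int(data["n_weeks"]),
            growth=GrowthSpec(**data.get("growth", {})),
            volume_seasonality=float(data.get("volume_seasonality", 0.25)),
            reference=ReferenceQuery(**data.get("reference", {})),
            diseases=tuple(
                DiseaseQuery(
                    label=d["label"], base_share=float(d["base_share"]),
                    token_form=d.get("token_form", ""),
                    compound_forms=tuple(d.get("compound_forms", ())),
                    phrase_forms=tuple(d.get("phrase_forms", ())),
                    token_weight=float(d.get("token_weight", 0.45)),
                    compound_weight=float(d.get("compound_weight", 0.35)),
                    phrase_weight=float(d.get("phrase_weight", 0.20)),
                    token_epidemic_coupling=float(d.get("token_epidemic_coupling", 0.4)),
                    epidemics=tuple(EpidemicEvent(WeekId.parse(e["peak_week"]),
                                                  float(e["width"]), float(e["height"]))
                                    for e in d.get("epidemics", ())),
                ) for d in data.get("diseases", ())),
            media_events=tuple(MediaEvent(m["topic"], WeekId.parse(m["week"]),
                                          float(m["height"]), float(m["decay"]))
                               for m in data.get("media_events", ())),
            media_effect=float(data.get("media_effect", 0.5)),
            media_baseline=float(data.get("media_baseline", 2.0)),
            overdispersion=data.get("overdispersion"),
            gaps=tuple((date.fromisoformat(a), date.fromisoformat(b))
                       for a, b in data.get("gaps", ())),
            seed=int(data.get("seed", 2005)),
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False, allow_unicode=True),
                        encoding="utf-8")
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


def default_scenario(seed: int | None = None) -> Scenario:
    """The stock five-year world: logistic 5-fold growth, winter-high
    volume, a growth-only reference, one compound-rich winter-epidemic
    disease with a media spike, and one five-week missing-log gap."""
    scenario = Scenario(
        start_week=WeekId(2005, 27),
        n_weeks=260,
        growth=GrowthSpec("logistic", 500.0, 2500.0),
        volume_seasonality=0.25,
        reference=ReferenceQuery("herpes", 0.04),
        diseases=(
            DiseaseQuery(
                label="kräk",
                base_share=0.02,
                token_form="kräkningar",
                compound_forms=("kräksjuka", "projektilkräkningar", "kräkkänsla"),
                phrase_forms=("kräkningar barn", "kräkningar och diarré"),
                epidemics=(EpidemicEvent(WeekId(2009, 2), width=3.0, height=8.0),),
            ),
        ),
        media_events=(MediaEvent("kräk", WeekId(2009, 47), height=40.0, decay=2.0),),
        gaps=((date(2006, 6, 5), date(2006, 7, 9)),),  # five weeks of missing logs
        seed=2005,
    )
    if seed is not None:
        scenario = replace(scenario, seed=int(seed))
    return scenario


@dataclass
class GroundTruth:
    """What was injected: expectations, factors, and realized counts."""

    weeks: list[WeekId]
    expected: pd.DataFrame           # per-week expected counts per column
    epidemic_factor: dict[str, np.ndarray]
    media_expected: dict[str, np.ndarray]
    gap_weeks: set[WeekId]
    realized: pd.DataFrame | None = None

    def expected_series(self, column: str) -> WeeklySeries:
        return WeeklySeries(column, self.weeks, self.expected[column].to_numpy(),
                            ValueKind.NORMALIZED)


def _media_expected_curve(scenario: Scenario, topic: str) -> np.ndarray:
    t = np.arange(scenario.n_weeks, dtype=float)
    curve = np.full(scenario.n_weeks, scenario.media_baseline)
    for event in scenario.media_events:
        if event.topic != topic:
            continue
        offset = event.week - scenario.start_week
        curve += event.height * np.exp(-np.abs(t - offset) / event.decay)
    return curve


def _epidemic_factor(scenario: Scenario, disease: DiseaseQuery) -> np.ndarray:
    t = np.arange(scenario.n_weeks, dtype=float)
    factor = np.ones(scenario.n_weeks)
    for event in disease.epidemics:
        offset = event.peak_week - scenario.start_week
        factor += (event.height - 1.0) * np.exp(-0.5 * ((t - offset) / event.width) ** 2)
    return factor


def expected_weekly_counts(scenario: Scenario) -> GroundTruth:
    """Deterministic skeleton of the generator: expected counts per week.

    Total volume is growth × (1 + seasonal cosine); the reference is a
    constant share of the growth curve alone (no seasonality); each
    disease form is its share of total volume times its (coupled)
    epidemic factor times the media-attention factor; the background
    absorbs the remainder so per-week expectations are conserved.
    """
    scenario.validate()
    weeks = scenario.weeks
    growth = scenario.growth.curve(scenario.n_weeks)
    doy = np.array([(w.monday + timedelta(days=3)).timetuple().tm_yday for w in weeks], dtype=float)
    season = 1.0 + scenario.volume_seasonality * np.cos(
        2.0 * math.pi * (doy - _WINTER_PEAK_DOY) / 365.25)
    total = growth * season

    columns: dict[str, np.ndarray] = {"total": total}
    columns[scenario.reference.label] = growth * scenario.reference.share

    epidemic_factor: dict[str, np.ndarray] = {}
    media_expected: dict[str, np.ndarray] = {
        topic: _media_expected_curve(scenario, topic)
        for topic in {m.topic for m in scenario.media_events}
    }
    disease_totals = np.zeros(scenario.n_weeks)
    for disease in scenario.diseases:
        factor = _epidemic_factor(scenario, disease)
        epidemic_factor[disease.label] = factor
        articles = media_expected.get(disease.label)
        media_factor = (1.0 + scenario.media_effect * articles / 100.0
                        if articles is not None else np.ones(scenario.n_weeks))
        label_total = np.zeros(scenario.n_weeks)
        token_total = np.zeros(scenario.n_weeks)
        token_forms = disease.token_matchable()
        for form, weight, coupling in disease.forms():
            mean = (total * disease.base_share * weight
                    * (1.0 + (factor - 1.0) * coupling) * media_factor)
            columns[f"{disease.label}|{form}"] = mean
            label_total += mean
            if form in token_forms:
                token_total += mean
        columns[disease.label] = label_total
        columns[f"{disease.label}:token"] = token_total
        disease_totals += label_total

    background = total - columns[scenario.reference.label] - disease_totals
    if np.any(background < 0):
        raise ValidationError("query shares (with epidemic/media inflation) exceed total volume")
    columns["background"] = background
    expected = pd.DataFrame(columns, index=pd.RangeIndex(scenario.n_weeks))

    gap_weeks = set()
    for start, stop in scenario.gaps:
        day = start
        while day <= stop:
            gap_weeks.add(WeekId.from_date(day))
            day += timedelta(days=7)
        gap_weeks.add(WeekId.from_date(stop))
    gap_weeks &= set(weeks)
    return GroundTruth(weeks=weeks, expected=expected, epidemic_factor=epidemic_factor,
                       media_expected=media_expected, gap_weeks=gap_weeks)


def _draw_counts(rng: np.random.Generator, mean: float, overdispersion: float | None) -> int:
    if mean <= 0:
        return 0
    if overdispersion is None:
        return int(rng.poisson(mean))
    # Gamma-Poisson mixture: variance = mean + mean^2 / overdispersion.
    return int(rng.poisson(rng.gamma(overdispersion, mean / overdispersion)))


def _emit(rng: np.random.Generator, week: WeekId, text: str, count: int,
          entries: list[QueryLogEntry]) -> None:
    if count <= 0:
        return
    seconds = rng.integers(0, 7 * 86400, size=count)
    styles = rng.random(count)
    base = datetime.combine(week.start, time())
    for s, style in zip(seconds, styles):
        shown = text
        if style < 0.05:
            shown = text.upper()
        elif style < 0.15:
            shown = text.capitalize()
        entries.append(QueryLogEntry(base + timedelta(seconds=int(s)), shown))


def generate_logs(scenario: Scenario) -> tuple[list[QueryLogEntry], GroundTruth]:
    """Draw a full synthetic log and its ground truth.

    Per non-gap week, each query stream draws a Poisson (or gamma-Poisson)
    count around its expectation and emits that many entries at uniform
    random times within the week; about 15% of entries carry case
    variation to exercise case-insensitive matching. Entries are returned
    time-sorted. Weeks inside declared gaps emit nothing.
    """
    truth = expected_weekly_counts(scenario)
    rng = np.random.default_rng(scenario.seed)
    entries: list[QueryLogEntry] = []
    realized_rows = []
    form_columns = [c for c in truth.expected.columns if "|" in c]
    lexicon = _BACKGROUND_LEXICON
    token_forms = {d.label: d.token_matchable() for d in scenario.diseases}

    for i, week in enumerate(truth.weeks):
        row = {"total": 0, "background": 0, scenario.reference.label: 0}
        for disease in scenario.diseases:
            row[disease.label] = 0
            row[f"{disease.label}:token"] = 0
        if week not in truth.gap_weeks:
            n_ref = _draw_counts(rng, truth.expected.at[i, scenario.reference.label],
                                 scenario.overdispersion)
            _emit(rng, week, scenario.reference.label, n_ref, entries)
            row[scenario.reference.label] = n_ref
            row["total"] += n_ref
            for column in form_columns:
                label, form = column.split("|", 1)
                n = _draw_counts(rng, truth.expected.at[i, column], scenario.overdispersion)
                _emit(rng, week, form, n, entries)
                row[label] += n
                row["total"] += n
                if form in token_forms[label]:
                    row[f"{label}:token"] += n
            n_bg = _draw_counts(rng, truth.expected.at[i, "background"],
                                scenario.overdispersion)
            if n_bg:
                words = rng.integers(0, len(lexicon), size=n_bg)
                counts = np.bincount(words, minlength=len(lexicon))
                for word, count in zip(lexicon, counts):
                    _emit(rng, week, word, int(count), entries)
            row["background"] = n_bg
            row["total"] += n_bg
        realized_rows.append(row)

    entries.sort(key=lambda e: e.timestamp)
    truth.realized = pd.DataFrame(realized_rows, index=pd.RangeIndex(scenario.n_weeks))
    return entries, truth


def generate_media_counts(scenario: Scenario, topic: str) -> WeeklySeries:
    """Realized weekly article counts for a topic (Poisson around the
    attention curve), independent of the log stream's random state."""
    truth_curve = _media_expected_curve(scenario, topic)
    rng = np.random.default_rng([scenario.seed, 311, sum(topic.encode())])
    counts = rng.poisson(truth_curve)
    scenario_weeks = scenario.weeks
    return WeeklySeries(topic, scenario_weeks, counts.astype(float), ValueKind.RAW_COUNT)


def generate_external_scaled(scenario: Scenario, label: str,
                             curiosity_noise: float = 0.0,
                             seed: int | None = None) -> WeeklySeries:
    """Emulate an external 0–100 relative-volume feed for a disease label.

    The feed sees the same epidemic signal but through a general-purpose
    search engine: media attention and idle curiosity add noise that
    obscures the epidemiological link. ``curiosity_noise`` scales both the
    media-driven and the white component; at 0 the feed is a clean
    rescaling of the injected epidemic excursion. Weeks are Sunday-start.
    """
    truth = expected_weekly_counts(scenario)
    if label not in truth.epidemic_factor:
        raise ValidationError(f"no disease labeled {label!r} in scenario")
    signal = truth.epidemic_factor[label] - 1.0
    rng = np.random.default_rng(seed if seed is not None
                                else [scenario.seed, 977, sum(label.encode())])
    scale = float(signal.std()) or 1.0
    articles = truth.media_expected.get(label)
    media_component = (articles / articles.max() if articles is not None
                       else np.zeros(scenario.n_weeks))
    noisy = (signal
             + curiosity_noise * media_component * float(signal.max() or 1.0) * 0.5
             + curiosity_noise * scale * rng.standard_normal(scenario.n_weeks))
    noisy = np.clip(noisy, 0.0, None)
    peak = noisy.max()
    if peak <= 0:
        raise ValidationError("external signal is identically zero")
    sunday_weeks = [WeekId(w.iso_year, w.week, WeekConvention.SUNDAY_START)
                    for w in scenario.weeks]
    scaled = np.minimum(noisy * (100.0 / peak), 100.0)
    return WeeklySeries(label, sunday_weeks, scaled, ValueKind.SCALED_0_100)
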