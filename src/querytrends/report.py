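"""Plot rendering and the weekly subscription runner.

Reports are files on disk: a PNG figure per request plus sidecar CSVs
that carry exactly the plotted data, so the figure's content is
verifiable bit-for-bit without image comparison. The subscription runner
replaces emailed graphs with the same report files written on a weekly
cadence; failures are isolated per job and summarized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import yaml

from .errors import QueryTrendsError, ValidationError
from .normalize import TrendModel
from .patterns import parse_pattern
from .trends import LogStore, TrendRequest, TrendResult, run_request
from .weeks import WeeklySeries, assign_week

logger = logging.getLogger(__name__)

__all__ = [
    "render_plot",
    "SubscriptionJob",
    "SubscriptionConfig",
    "SubscriptionReport",
    "run_subscriptions",
]

_LINE_STYLES = ["-", (0, (5, 2)), (0, (1, 1)), (0, (3, 1, 1, 1)), (0, (5, 1, 1, 1, 1, 1))]


def _series_sidecar(result: TrendResult, path: Path) -> list[Path]:
    paths = []
    for series in result.series:
        safe = "".join(c if c.isalnum() else "_" for c in series.label)
        sidecar = path.with_name(f"{path.stem}-{safe}.csv")
        series.to_csv(sidecar)
        paths.append(sidecar)
    if result.media is not None:
        sidecar = path.with_name(f"{path.stem}-media.csv")
        result.media.to_csv(sidecar)
        paths.append(sidecar)
    return paths


def render_plot(result: TrendResult, path: str | Path, *, dpi: int = 100,
                figsize: tuple[float, float] = (10.0, 5.0)) -> Path:
    """Render a trend result to PNG with sidecar CSVs of the plotted data.

    Normalized series get distinct line styles on the left axis; the
    media series, if present, is drawn on a twin right axis; the
    request-anniversary week of each year is marked with a dot. Output is
    deterministic for fixed input (fixed figure size, dpi and data).
    """
    if not result.series or all(len(s) == 0 for s in result.series):
        raise ValidationError("cannot render an empty trend result")
    path = Path(path)
    fig, ax = plt.subplots(figsize=figsize, dpi=dpi)
    for i, series in enumerate(result.series):
        x = [w.start for w in series.weeks]
        ax.plot(x, series.values, linestyle=_LINE_STYLES[i % len(_LINE_STYLES)],
                label=series.label)
        marks = [j for j, w in enumerate(series.weeks) if w in result.anniversary_weeks]
        ax.plot([x[j] for j in marks], [series.values[j] for j in marks],
                "o", color=ax.get_lines()[-1].get_color(), markersize=4)
    ax.set_ylabel("normalized query volume")
    ax.set_xlabel("week")
    if result.media is not None and len(result.media):
        twin = ax.twinx()
        twin.plot([w.start for w in result.media.weeks], result.media.values,
                  linestyle=(0, (1, 2)), color="black", label=f"media: {result.media.label}")
        twin.set_ylabel("media articles / week")
        handles, labels = ax.get_legend_handles_labels()
        h2, l2 = twin.get_legend_handles_labels()
        ax.legend(handles + h2, labels + l2, loc="upper left", fontsize=8)
    else:
        ax.legend(loc="upper left", fontsize=8)
    fig.autofmt_xdate()
    fig.savefig(path)
    plt.close(fig)
    _series_sidecar(result, path)
    return path


@dataclass(frozen=True)
class SubscriptionJob:
    """One standing request: patterns plus output formats."""

    name: str
    patterns: tuple[str, ...]
    formats: tuple[str, ...] = ("plot", "csv")
    include_media: bool = False
    media_topic: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.formats) - {"plot", "csv"}
        if bad:
            raise ValidationError(f"unknown report formats {sorted(bad)}")


@dataclass(frozen=True)
class SubscriptionConfig:
    jobs: tuple[SubscriptionJob, ...]
    output_dir: Path
    cadence: str = "weekly"

    def __post_init__(self) -> None:
        if self.cadence != "weekly":
            raise ValidationError("only weekly cadence is supported")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SubscriptionConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        jobs = tuple(SubscriptionJob(
            name=j["name"], patterns=tuple(j["patterns"]),
            formats=tuple(j.get("formats", ("plot", "csv"))),
            include_media=bool(j.get("include_media", False)),
            media_topic=j.get("media_topic"),
        ) for j in data["jobs"])
        return cls(jobs=jobs, output_dir=Path(data["output_dir"]),
                   cadence=data.get("cadence", "weekly"))


@dataclass
class SubscriptionReport:
    written: list[Path] = field(default_factory=list)
    failures: list[tuple[str, str]] = field(default_factory=list)  # (job, error)

    @property
    def ok(self) -> bool:
        return not self.failures


def run_subscriptions(config: SubscriptionConfig, now: date, store: LogStore,
                      trend: TrendModel, media: WeeklySeries | None = None) -> SubscriptionReport:
    """Run every job for the week containing ``now``.

    Report files are named after the job and the ISO week, so re-running
    within the same week overwrites rather than duplicates. One job's
    failure never aborts the others; failures are collected in the
    returned report.
    """
    request_week = assign_week(now)
    config.output_dir.mkdir(parents=True, exist_ok=True)
    report = SubscriptionReport()
    for job in config.jobs:
        try:
            request = TrendRequest(
                patterns=tuple(parse_pattern(p) for p in job.patterns),
                request_week=request_week,
                include_media=job.include_media,
                media_topic=job.media_topic,
            )
            result = run_request(request, store, trend, media=media)
            stem = f"{job.name}-{request_week}"
            if "plot" in job.formats:
                out = config.output_dir / f"{stem}.png"
                render_plot(result, out)
                report.written.append(out)
            if "csv" in job.formats:
                for series in result.series:
                    safe = "".join(c if c.isalnum() else "_" for c in series.label)
                    out = config.output_dir / f"{stem}-{safe}.csv"
                    series.to_csv(out)
                    report.written.append(out)
        except QueryTrendsError as exc:
            logger.error("subscription job %r failed: %s", job.name, exc)
            report.failures.append((job.name, str(exc)))
    return report
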