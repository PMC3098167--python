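"""Anonymous query-log files: reading, validation, writing.

A log records one search event per line: a timestamp and the raw query
text, nothing else. The anonymity contract is enforced structurally — the
:class:`QueryLogEntry` type has no other fields, and the reader drops any
extra columns an extended dialect may declare (IP addresses, session ids)
with a warning, so identity-bearing data never enters the pipeline.

The default on-disk dialect is UTF-8, one record per line,
``ISO-8601 datetime<TAB>query text``. Files ending in ``.gz`` are
decompressed transparently.
"""

from __future__ import annotations

import gzip
import io
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

from .errors import DialectError, EmptyQueryError, LogParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "QueryLogEntry",
    "LogDialect",
    "DEFAULT_DIALECT",
    "LogReadResult",
    "parse_log_line",
    "read_log",
    "write_log",
]


@dataclass(frozen=True, slots=True)
class QueryLogEntry:
    """One anonymous search event: when it happened and what was typed.

    Timestamps are naive local time at second resolution (sub-second parts
    are truncated); query text is kept byte-for-byte as submitted, except
    that it must be single-line and non-blank.
    """

    timestamp: datetime
    query_text: str

    def __post_init__(self) -> None:
        if not isinstance(self.timestamp, datetime):
            raise ValidationError(f"timestamp must be a datetime, got {type(self.timestamp).__name__}")
        if self.timestamp.microsecond:
            object.__setattr__(self, "timestamp", self.timestamp.replace(microsecond=0))
        if not self.query_text or not self.query_text.strip():
            raise ValidationError("query_text must be non-empty after stripping whitespace")
        if "\n" in self.query_text or "\r" in self.query_text:
            raise ValidationError("query_text must be single-line")


@dataclass(frozen=True)
class LogDialect:
    """How a log file is laid out on disk.

    ``extra_fields`` declares trailing columns beyond (timestamp, query)
    that some providers append; the reader discards them. With no extra
    fields the query field runs to end of line, so it may itself contain
    the separator.
    """

    separator: str = "\t"
    encoding: str = "utf-8"
    extra_fields: tuple[str, ...] = ()


DEFAULT_DIALECT = LogDialect()


def parse_log_line(line: str, dialect: LogDialect = DEFAULT_DIALECT, line_number: int | None = None) -> QueryLogEntry:
    """Parse one record; raises :class:`LogParseError` naming the line.

    An empty query field raises the :class:`EmptyQueryError` subclass so
    callers can count-and-skip rather than abort.
    """
    line = line.rstrip("\r\n")
    if dialect.extra_fields:
        parts = line.split(dialect.separator)
        if len(parts) < 2:
            raise LogParseError("expected at least 2 fields", line_number)
        ts_text, query = parts[0], parts[1]
    else:
        ts_text, sep, query = line.partition(dialect.separator)
        if not sep:
            raise LogParseError("missing field separator", line_number)
    try:
        timestamp = datetime.fromisoformat(ts_text)
    except ValueError:
        raise LogParseError(f"malformed timestamp {ts_text!r}", line_number) from None
    if not query.strip():
        raise EmptyQueryError("empty query field", line_number)
    return QueryLogEntry(timestamp, query)


@dataclass
class LogReadResult:
    """Entries read from a file plus bookkeeping about skipped lines."""

    entries: list[QueryLogEntry] = field(default_factory=list)
    skipped: int = 0
    path: Path | None = None

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def _open_text(path: Path, encoding: str, mode: str = "rt") -> io.TextIOBase:
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding=encoding)  # type: ignore[return-value]
    return open(path, mode, encoding=encoding)


def read_log(source: str | Path, dialect: LogDialect = DEFAULT_DIALECT) -> LogReadResult:
    """Read a log file, skipping (and counting) malformed lines.

    If more than half the lines are malformed the file is rejected with
    :class:`DialectError` — it is almost certainly in a different dialect.
    Extra columns declared by the dialect are dropped with a warning: only
    the timestamp and query text ever leave this function.
    """
    path = Path(source)
    result = LogReadResult(path=path)
    total = 0
    warned_extra = False
    with _open_text(path, dialect.encoding) as handle:
        for line_number, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            total += 1
            if dialect.extra_fields and not warned_extra:
                warnings.warn(
                    f"dialect declares extra fields {dialect.extra_fields}; "
                    "they are dropped to preserve anonymity",
                    stacklevel=2,
                )
                warned_extra = True
            try:
                result.entries.append(parse_log_line(line, dialect, line_number))
            except LogParseError as exc:
                result.skipped += 1
                logger.warning("skipping %s: %s", path.name, exc)
    if total and result.skipped > total / 2:
        raise DialectError(
            f"{result.skipped} of {total} lines malformed in {path} — wrong dialect?"
        )
    return result


def write_log(entries: Iterable[QueryLogEntry] | Sequence[QueryLogEntry],
              sink: str | Path,
              dialect: LogDialect = DEFAULT_DIALECT) -> int:
    """Write entries in the given dialect; returns the record count.

    Round-trips with :func:`read_log`: timestamps to the second, query
    text byte-identical.
    """
    path = Path(sink)
    count = 0
    with _open_text(path, dialect.encoding, "wt") as handle:
        for entry in entries:
            handle.write(entry.timestamp.isoformat(sep="T", timespec="seconds"))
            handle.write(dialect.separator)
            handle.write(entry.query_text)
            handle.write("\n")
            count += 1
    return count
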