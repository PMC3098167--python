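"""The generous query-pattern language: pipes and star wildcards.

A pattern is one or more alternatives separated by ``|``; each alternative
is a match string optionally flanked by ``*``. A bare alternative matches
as a whole whitespace-delimited token of the query; a ``*`` on a side
relaxes that side's boundary to "any characters, including none", so
``*kräk*`` matches Swedish compounds like *projektilkräkningar* as well as
multi-word queries. Matching is case-insensitive (full Unicode case
folding) but never accent-insensitive: spelling variants must be
enumerated with pipes, e.g. ``diarre|diarré``.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass
from typing import Iterable

from .errors import PatternSyntaxError
from .logs import QueryLogEntry

__all__ = ["Alternative", "QueryPattern", "parse_pattern", "matches", "count_matching"]


@dataclass(frozen=True, slots=True)
class Alternative:
    """One branch of a pattern: a lowercase core plus wildcard flags."""

    core: str
    prefix_wild: bool = False
    suffix_wild: bool = False

    def render(self) -> str:
        return ("*" if self.prefix_wild else "") + self.core + ("*" if self.suffix_wild else "")


@dataclass(frozen=True)
class QueryPattern:
    """A parsed user pattern; build with :func:`parse_pattern`.

    The special match-everything pattern (used for total site volume) has
    no alternatives and is obtained from :meth:`match_all`.
    """

    raw_text: str
    alternatives: tuple[Alternative, ...]

    @property
    def is_match_all(self) -> bool:
        return not self.alternatives

    @property
    def canonical(self) -> str:
        """Canonical rendering: lowercased cores joined by pipes."""
        if self.is_match_all:
            return "*"
        return "|".join(alt.render() for alt in self.alternatives)

    @classmethod
    def match_all(cls) -> "QueryPattern":
        return cls(raw_text="*", alternatives=())

    def __str__(self) -> str:
        return self.canonical


def parse_pattern(text: str) -> QueryPattern:
    """Parse ``alt1|alt2|...`` with optional ``*`` flanks per alternative.

    Raises :class:`PatternSyntaxError` for empty alternatives (including a
    ``|`` at either end of the string) and for alternatives that are only
    stars.
    """
    if not text or not text.strip():
        raise PatternSyntaxError("pattern is empty")
    alternatives = []
    for part in text.split("|"):
        stripped = part.strip()
        if not stripped:
            raise PatternSyntaxError(f"empty alternative in pattern {text!r}")
        prefix_wild = stripped.startswith("*")
        rest = stripped[1:] if prefix_wild else stripped
        suffix_wild = rest.endswith("*")
        core = rest[:-1] if suffix_wild else rest
        core = core.strip().casefold()
        if not core:
            raise PatternSyntaxError(f"alternative {stripped!r} has no match string")
        alternatives.append(Alternative(core, prefix_wild, suffix_wild))
    return QueryPattern(raw_text=text, alternatives=tuple(alternatives))


def _alternative_regex(alt: Alternative) -> str:
    # A non-wild side must sit on a token boundary (string edge or
    # whitespace); a starred side accepts anything, including nothing.
    left = "" if alt.prefix_wild else r"(?:^|(?<=\s))"
    right = "" if alt.suffix_wild else r"(?:$|(?=\s))"
    return left + re.escape(alt.core) + right


@functools.lru_cache(maxsize=1024)
def _compiled(pattern: QueryPattern) -> re.Pattern[str]:
    return re.compile("|".join(_alternative_regex(alt) for alt in pattern.alternatives))


def matches(pattern: QueryPattern, query_text: str) -> bool:
    """True iff any alternative matches the case-folded query text."""
    if pattern.is_match_all:
        return True
    return _compiled(pattern).search(query_text.casefold()) is not None


def count_matching(pattern: QueryPattern, entries: Iterable[QueryLogEntry]) -> int:
    """Number of entries matching the pattern (each entry counted once)."""
    if pattern.is_match_all:
        return sum(1 for _ in entries)
    regex = _compiled(pattern)
    return sum(1 for entry in entries if regex.search(entry.query_text.casefold()))
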