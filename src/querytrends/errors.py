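"""Exception hierarchy shared across the package."""


class QueryTrendsError(Exception):
    """Base class for all errors raised by this package."""


class LogParseError(QueryTrendsError):
    """A log line could not be parsed in the declared dialect."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class EmptyQueryError(LogParseError):
    """The query field of a log line is empty (skippable, not fatal)."""


class DialectError(QueryTrendsError):
    """The file as a whole does not look like the declared dialect."""


class PatternSyntaxError(QueryTrendsError):
    """A query pattern string violates the star/pipe pattern language."""


class ValidationError(QueryTrendsError):
    """An input value violates a documented contract."""


class FitError(QueryTrendsError):
    """The trend smoother cannot be fitted to the given series."""


class EmptyOverlapError(QueryTrendsError):
    """Two or more series have no weeks in common."""


class InsufficientDataError(QueryTrendsError):
    """Not enough observations to compute the requested statistic."""
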