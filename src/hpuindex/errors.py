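"""Exception hierarchy shared across the pipeline.

Every error carries an ``exit_code`` so the command-line surface can map
failures onto stable shell exit statuses: 2 for validation problems,
3 for I/O problems, 4 for degenerate data (constant series, empty months).
"""

from __future__ import annotations


class HPUError(Exception):
    """Base class for all package errors."""

    exit_code = 2


class ValidationError(HPUError):
    """Input violates a structural invariant (shape, range, roster ...)."""

    exit_code = 2


class ParseError(ValidationError):
    """A record in an input file could not be parsed.

    ``line`` is the 1-based line (JSONL) or row (CSV) number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EmptyCorpusError(ValidationError):
    """The corpus contains no articles."""


class InputOutputError(HPUError):
    """Filesystem-level failure (missing path, unwritable directory)."""

    exit_code = 3


class DegenerateDataError(HPUError):
    """Data is formally valid but statistically unusable."""

    exit_code = 4


class DegenerateSeriesError(DegenerateDataError):
    """A newspaper's scaled-frequency series is constant (sigma = 0) or
    has fewer than two observed months, so unit-SD standardization is
    undefined."""


class EmptyMonthError(DegenerateDataError):
    """A month has no covered newspaper, so the cross-paper mean is
    undefined."""


class InsufficientOverlapError(DegenerateDataError):
    """Two series share fewer than three months, so a Pearson correlation
    cannot be computed."""
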