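"""Validation errors with machine-readable codes.

Every error raised by the public API carries a short ``code`` string so
that callers (and the CLI) can react programmatically, plus a
human-readable message that names the offending country/indicator cell
where one is known.
"""

from __future__ import annotations


class NinescoreError(ValueError):
    """Base class for all validation failures in this package."""

    code: str = "error"

    def __init__(self, message: str):
        super().__init__(message)
        self.message = message

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"[{self.code}] {self.message}"


class InvalidInputError(NinescoreError):
    """A raw value is non-finite or otherwise unusable."""

    code = "invalid-input"


class InvalidScoreError(NinescoreError):
    """An indicator score is outside {1, 2, 3}."""

    code = "invalid-score"


class InvalidTotalError(NinescoreError):
    """A domain total is outside the attainable range [3, 9]."""

    code = "invalid-total"


class InvalidRatingError(NinescoreError):
    """A rating string is not one of the ten sorted A/B/C combinations."""

    code = "invalid-rating"


class MissingDataError(NinescoreError):
    """An indicator has neither a raw value nor a direct score.

    Identifies the (country, indicator) cell so it can be referred to a
    Delphi panel.
    """

    code = "missing-data"


class ConflictError(NinescoreError):
    """A Delphi consensus targets a cell that already holds a value."""

    code = "delphi-conflict"


class NoResponsesError(NinescoreError):
    """A Delphi ballot contains no votes."""

    code = "no-responses"


class TableFormatError(NinescoreError):
    """An input table is malformed; message carries row/column coordinates."""

    code = "table-format"
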