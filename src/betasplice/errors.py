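"""Exception hierarchy shared across the package."""


class BetaSpliceError(Exception):
    """Base class for all package errors."""


class InputValidationError(BetaSpliceError, ValueError):
    """A value violates a domain invariant (negative count, bad threshold...)."""


class ParseError(InputValidationError):
    """A table cell or row could not be interpreted; carries row/column context."""

    def __init__(self, message: str, *, row: int | None = None, column: str | None = None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.row = row
        self.column = column


class ConfigError(BetaSpliceError, ValueError):
    """Inconsistent study design or run configuration."""
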