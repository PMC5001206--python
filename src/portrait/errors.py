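"""Exception hierarchy shared across the package."""


class PortraitError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PortraitError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SchemaError(PortraitError):
    """A table is missing mandatory columns."""


class ValidationError(PortraitError):
    """A parsed value violates a data-model invariant."""


class InsufficientOverlapError(PortraitError):
    """Too few shared features/samples to compute a correlation."""


class UndefinedResultError(PortraitError):
    """The requested statistic is undefined on this input (empty/constant)."""
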