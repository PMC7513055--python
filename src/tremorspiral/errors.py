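"""Exception hierarchy shared across the package."""


class TremorSpiralError(Exception):
    """Base class for all package-specific errors."""


class SVCParseError(TremorSpiralError):
    """A line of an SVC file could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class IntegrityError(TremorSpiralError):
    """File-level inconsistency: count mismatch, non-monotone timestamps."""


class ValidationError(TremorSpiralError):
    """A domain object violates its invariants or an argument is invalid."""


class InsufficientDataError(TremorSpiralError):
    """A signal is too short for the requested computation."""
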