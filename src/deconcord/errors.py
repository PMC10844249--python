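"""Exception hierarchy shared across the package.

Every anticipated failure mode maps onto one of these classes so that the
CLI can translate them into a stable exit-code discipline (validation and
configuration problems exit 2, anything unexpected exits 1).
"""


class DeconcordError(Exception):
    """Base class for all anticipated errors raised by this package."""


class ValidationError(DeconcordError):
    """Input data violates a documented invariant."""


class ConfigurationError(DeconcordError):
    """A configuration value or requested column/statistic is missing or inconsistent."""


class ParseError(DeconcordError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class DegenerateInputError(DeconcordError):
    """Numerically degenerate input (zero variance, zero residual SD, ...)."""
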