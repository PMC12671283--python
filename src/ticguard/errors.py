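"""Exception hierarchy shared across the package."""


class TicGuardError(Exception):
    """Base class for all package errors."""


class StreamParseError(TicGuardError):
    """A sensor/token/button file could not be parsed; names the line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class StreamValidationError(TicGuardError):
    """A stream violates a structural invariant (e.g. decreasing time)."""


class InsufficientDataError(TicGuardError):
    """Not enough samples/points for the requested operation."""


class NotFittedError(TicGuardError):
    """A model or baseline was used before fitting."""


class DegenerateFitError(TicGuardError):
    """A regression cannot be fit (e.g. all timestamps identical)."""


class ConfigError(TicGuardError):
    """A configuration value is structurally invalid."""
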