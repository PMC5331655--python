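"""Exception types shared across the package."""


class TeconsexError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TeconsexError):
    """An invalid configuration value; ``field`` names the offending entry."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class ParseError(TeconsexError):
    """A malformed input record; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(TeconsexError, ValueError):
    """An argument outside its documented domain."""


class UndefinedStatisticError(TeconsexError):
    """A ratio or proportion whose denominator is empty (e.g. zero lifted
    instances); signalled distinctly so callers can report it as missing
    rather than as 0 or NaN."""
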