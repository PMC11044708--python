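"""Exception hierarchy for the sowlying pipeline."""


class SowlyingError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SowlyingError, ValueError):
    """A file could not be parsed (bad timestamp, malformed row, ...)."""


class ConfigError(SowlyingError, ValueError):
    """A configuration value is missing or inconsistent."""


class ValidationError(SowlyingError, ValueError):
    """An input table violates a structural invariant (overlap, order, ...)."""


class ParameterError(SowlyingError, ValueError):
    """An algorithm parameter is outside its legal range."""


class DegenerateMatrixError(SowlyingError, ArithmeticError):
    """A ratings matrix has zero total variance; the ICC is undefined."""
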