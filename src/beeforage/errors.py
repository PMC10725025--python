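"""Exception hierarchy. Each class maps to a distinct CLI exit code."""


class BeeforageError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(BeeforageError):
    """An input table is missing required columns or has malformed values."""

    exit_code = 2


class ConfigError(BeeforageError):
    """A configuration value is out of its allowed domain."""

    exit_code = 3


class ConvergenceError(BeeforageError):
    """A model fit failed to converge; carries the optimizer message."""

    exit_code = 4


class MissingWindowError(BeeforageError):
    """A required choice window is absent for one or more bees."""

    exit_code = 5


class ValidationError(BeeforageError):
    """Event data violates a structural invariant."""

    exit_code = 6


class DomainError(BeeforageError):
    """A physiological relation was evaluated outside its valid domain."""

    exit_code = 7


class UnsupportedConcentrationError(DomainError):
    """No drinking-rate model exists for the requested concentration."""

    exit_code = 7


class UndefinedCurrencyError(BeeforageError):
    """A currency was requested with a zero denominator."""

    exit_code = 8
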