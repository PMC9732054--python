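"""Exception types shared across the pipeline."""


class LulcstError(Exception):
    """Base class for all package errors."""


class ArgumentError(LulcstError, ValueError):
    """An argument violates an operation's preconditions."""


class ConfigError(LulcstError, ValueError):
    """A configuration or metadata file is missing or malformed."""


class NumericalError(LulcstError, ArithmeticError):
    """A numerical step failed (e.g. a singular covariance matrix)."""
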