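"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`AdoptsimError`, so callers can catch one type at pipeline level.
"""


class AdoptsimError(Exception):
    """Base class for all errors raised by adoptsim."""


class ConfigurationError(AdoptsimError, ValueError):
    """Invalid configuration value or combination of values."""


class DataError(AdoptsimError, ValueError):
    """Input data violates a precondition (shapes, ids, missingness...)."""


class DegenerateFitError(AdoptsimError, ValueError):
    """A model fit is degenerate (perfect fit, separation, rank deficiency)."""


class ConvergenceError(AdoptsimError, RuntimeError):
    """An iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


class ParseError(AdoptsimError, ValueError):
    """A flat file could not be parsed; names the offending line."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line
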