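"""Exception types shared across the package.

Exit-code mapping used by the command line interface:
configuration problems -> 2, data problems -> 3.
"""


class FNTDoseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FNTDoseError):
    """A configuration value or file is invalid.  The message names the
    offending field."""


class DataError(FNTDoseError):
    """Input data are structurally invalid (missing columns, bad rows)."""


class DomainError(FNTDoseError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class FitError(FNTDoseError, RuntimeError):
    """A model fit failed to converge or is degenerate.  Carries the
    initial guesses and residual norm where available."""

    def __init__(self, message, *, p0=None, residual_norm=None):
        super().__init__(message)
        self.p0 = p0
        self.residual_norm = residual_norm
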