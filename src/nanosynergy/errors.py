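"""Exception hierarchy for the screening pipeline.

Every stage raises a subclass of :class:`NanosynergyError`, so callers (and
the CLI) can distinguish user/data problems from genuine bugs.
"""


class NanosynergyError(Exception):
    """Base class for all package errors."""


class DesignError(NanosynergyError):
    """Invalid factorial design specification (duplicate drugs, bad levels...)."""


class CapacityError(DesignError):
    """More conditions than plate positions."""


class ConfigError(NanosynergyError):
    """Invalid simulation or run configuration."""


class SchemaError(NanosynergyError):
    """A delimited-text input is missing required columns or has bad values."""

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column


class NormalizationError(NanosynergyError):
    """Control intensities unusable (zero or negative mean)."""


class InsufficientDataError(NanosynergyError):
    """Too few usable points for a fit."""


class DegenerateFitError(NanosynergyError):
    """Response carries no dose information (e.g. flat viability)."""


class NumericalError(NanosynergyError):
    """Root-finding or optimisation failed with a diagnostic."""


class SingularModelError(NanosynergyError):
    """Rank-deficient regression design matrix."""

    def __init__(self, message: str, terms: list[str] | None = None):
        super().__init__(message)
        self.terms = terms or []


class SelectionError(NanosynergyError):
    """No eligible cocktail for the requested potent-drug set."""
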