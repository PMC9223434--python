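"""Exception hierarchy shared across the package."""


class AucsensError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AucsensError):
    """A model, trajectory or analysis argument violates its contract."""


class ConfigurationError(AucsensError):
    """A configuration document is malformed; message names the offending field."""


class IntegrationError(AucsensError):
    """The ODE solver failed (non-convergence or non-finite states).

    Carries the parameter map that triggered the failure so batch callers
    can report which perturbation broke the integration.
    """

    def __init__(self, message: str, params: dict | None = None):
        super().__init__(message)
        self.params = dict(params) if params else {}


class UndefinedIndexError(AucsensError):
    """The nominal output AUC is at or below the numerical floor.

    The sensitivity index S divides by the nominal AUC; when the chosen
    output variable never rises above zero under nominal conditions the
    index (and the whole ranking for that output) is meaningless.
    """


class NumericalAnomalyError(AucsensError):
    """A quantity left its physically admissible range (e.g. A + 1 < 0)."""
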