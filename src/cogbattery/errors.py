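"""Exception hierarchy for the cognitive battery toolkit."""


class CogBatteryError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CogBatteryError, ValueError):
    """A precondition on an operation's arguments was violated."""


class IncompleteSessionError(CogBatteryError):
    """A response log ends before the test administration is complete."""


class LayoutInfeasibleError(CogBatteryError):
    """Requested circle geometry cannot be packed into the layout space."""


class InvalidConfigError(CogBatteryError, ValueError):
    """A configuration file or block failed validation."""


class InsufficientDataError(CogBatteryError):
    """Too few observations to compute the requested statistic."""


class UndefinedStatisticError(CogBatteryError):
    """The statistic is undefined for this input (e.g. zero variance)."""


class FitFailureError(CogBatteryError):
    """A model fit did not converge; carries diagnostics in ``args``."""


class DegenerateDesignError(CogBatteryError):
    """The longitudinal design cannot identify the requested model."""
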