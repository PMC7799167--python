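"""Exception hierarchy shared across the package."""


class PrevprojError(Exception):
    """Base class for all package-specific errors."""


class ScheduleIncompleteError(PrevprojError, ValueError):
    """A survival schedule or rate table does not cover the requested ages/years."""


class CalibrationError(PrevprojError, RuntimeError):
    """A mortality-scaling target cannot be reached within admissible bounds."""


class UndefinedRatioError(PrevprojError, ZeroDivisionError):
    """A ratio with an empty denominator was requested."""


class ContractViolationError(PrevprojError, ValueError):
    """An input violates a model precondition (e.g. md > sr)."""


class DivisionUndefinedError(PrevprojError, ZeroDivisionError):
    """Prevalence recursion is undefined because the survival rate is zero."""


class DataIntegrityError(PrevprojError, ValueError):
    """A claims panel contains structurally invalid records."""


class ConfigurationError(PrevprojError, ValueError):
    """An unknown scenario, disease or variant name was requested."""
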