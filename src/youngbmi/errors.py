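"""Exception hierarchy for the youngbmi package."""


class YoungBMIError(Exception):
    """Base class for all package errors."""


class ConfigError(YoungBMIError):
    """Invalid simulation or analysis configuration."""


class DomainError(YoungBMIError):
    """An input value outside the physical/mathematical domain of an operation."""


class TooFewPointsError(YoungBMIError):
    """A series is too short for LOWESS smoothing (fewer than 4 points)."""


class IneligibleSubjectError(YoungBMIError):
    """Subject lacks the measurements required by the eligibility rule."""


class CohortLoadError(YoungBMIError):
    """A cohort CSV failed validation; message lists the offending rows/columns."""


class FitError(YoungBMIError):
    """A trend fit could not be computed (e.g. rank-deficient design)."""
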