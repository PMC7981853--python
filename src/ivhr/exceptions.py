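"""Exception hierarchy for ivhr.

All errors raised deliberately by the package derive from :class:`IVHRError`
so callers can catch the package's failures with a single except clause.
"""


class IVHRError(Exception):
    """Base class for all ivhr errors."""


class InputDataError(IVHRError):
    """A data file or array violates the input contract (bad column, value, row)."""


class DegenerateDataError(IVHRError):
    """The sample cannot support the requested estimation.

    Raised when there are no events, or when the exposure or the instrument
    is constant so the estimating equations are identically zero or singular.
    """


class NumericalError(IVHRError):
    """A numerical failure that is not a data-contract violation.

    Example: the risk-set weight sum underflowing to zero at an event time.
    """


class CalibrationError(IVHRError):
    """The censoring-scale calibration cannot attain the requested rate."""


class DefectiveDistributionError(IVHRError):
    """The treated time-to-event distribution has finite total hazard.

    A log-linear hazard ratio with negative slope against a unit-exponential
    baseline yields a cumulative hazard bounded above; probability mass beyond
    that bound never fails, so the inverse CDF is undefined there.
    """


class CIFailureError(IVHRError):
    """Bootstrap confidence-interval construction failed (too many refits diverged)."""
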