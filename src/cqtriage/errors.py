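"""Exception hierarchy for the cqtriage pipeline.

CLI exit-code convention: ConfigurationError family -> 2, DataError family -> 3.
"""


class CqTriageError(Exception):
    """Base class for all cqtriage errors."""


class ConfigurationError(CqTriageError):
    """Invalid configuration: bad panel, missing adequacy target, bad strategy..."""


class DataError(CqTriageError):
    """Invalid or inconsistent input data."""


class ParseError(DataError):
    """Malformed cell in an input table; message names the row and column."""


class DuplicateMeasurementError(DataError):
    """The same (sample, target, replicate) appears more than once."""


class DegenerateContrastError(DataError):
    """A contrast with zero positives or zero negatives."""


class MissingFeatureError(DataError):
    """A pair target has no measurement for one or more samples."""


class InfeasibleStrategyError(CqTriageError):
    """No cutoff satisfies the diagnostic strategy's constraints.

    Carries the best attainable operating point in ``best_operating_point``
    as a (sensitivity, specificity) tuple in percent.
    """

    def __init__(self, message: str, best_operating_point=None):
        super().__init__(message)
        self.best_operating_point = best_operating_point


class UndefinedCVError(CqTriageError):
    """Coefficient of variation requested for values with zero mean."""


class DegenerateScaleError(CqTriageError):
    """Heat-map scale requested for fewer than three distinct values."""


class UndefinedCorrelationError(CqTriageError):
    """Rank correlation requested for a constant vector."""
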