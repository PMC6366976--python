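"""Exception hierarchy shared across the package.

Every error raised on a documented failure path derives from
:class:`GrimclockError`, so callers (and the CLI) can distinguish
"the input violated a precondition" from a genuine bug.
"""


class GrimclockError(Exception):
    """Base class for all documented grimclock failures."""


class InvalidArgumentError(GrimclockError, ValueError):
    """An argument violated a documented precondition."""


class ImputationError(GrimclockError):
    """A column could not be median-imputed (fully missing, no reference)."""


class DegenerateTargetError(GrimclockError):
    """The regression target carries no variation."""


class MissingFeatureError(GrimclockError):
    """Features required by a model are absent from the input matrix."""

    def __init__(self, feature_ids, message=None):
        self.feature_ids = list(feature_ids)
        super().__init__(
            message or f"features not resolvable in input: {self.feature_ids}"
        )


class NoEventsError(GrimclockError):
    """A survival fit was requested on data without observed events."""


class DegenerateCalibrationError(GrimclockError):
    """The linear predictor has zero variance; year calibration undefined."""


class DegenerateRegressionError(GrimclockError):
    """Age has zero variance; residualization undefined."""


class NoVariationError(GrimclockError):
    """A predictor is constant; an association fit is undefined."""


class ConvergenceError(GrimclockError):
    """A survival model failed to converge (e.g. separation, collinearity)."""


class UndefinedCorrelationError(GrimclockError):
    """A correlation is undefined (zero spread in one of the vectors)."""


class TieResolutionError(GrimclockError):
    """Quantile tails overlap because of tied predictor values."""


class NoEstimableStrataError(GrimclockError):
    """Every stratum failed the per-stratum fit preconditions."""


class SchemaError(GrimclockError):
    """A table is missing required columns or holds ill-typed values."""


class ParseError(GrimclockError):
    """A delimited file could not be parsed; message carries the location."""


class ValidationError(GrimclockError):
    """Parsed values violate a range or uniqueness rule."""
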