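"""Error types raised across the pipeline.

Each error corresponds to a violated precondition of one pipeline stage,
so callers can distinguish data problems (e.g. a column missing from the
catalog) from degenerate statistical situations (e.g. a fold without both
outcome classes).
"""


class PCMRiskError(Exception):
    """Base class for all package errors."""


class UnknownVariable(PCMRiskError):
    """A table column is not declared in the feature catalog."""


class LevelMismatch(PCMRiskError):
    """A categorical cell holds a value outside the declared levels."""


class MissingValues(PCMRiskError):
    """An operation requiring complete data received unimputed cells."""


class ExcessMissingness(PCMRiskError):
    """A variable's missing fraction exceeds the configured ceiling."""


class MissingFlag(PCMRiskError):
    """A baseline diagnosis flag needed for subgroup assignment is absent."""


class DegenerateConfig(PCMRiskError):
    """Generator calibration cannot reach the requested target."""


class SingleClassFold(PCMRiskError):
    """A training split contains only one outcome class."""


class FeatureMismatch(PCMRiskError):
    """Prediction input columns do not match the fitted model."""


class MissingScoreVariable(PCMRiskError):
    """An external score references a variable absent from the cohort."""


class TooFewSamples(PCMRiskError):
    """Not enough samples per class for the requested estimator."""


class InvalidThreshold(PCMRiskError):
    """Decision threshold outside the open interval (0, 1)."""


class NonTreeModel(PCMRiskError):
    """Attribution requested for a model that is not a tree ensemble."""


class DegenerateGroups(PCMRiskError):
    """High/low risk groups too small for an effect-size computation."""


class ConstantMarker(PCMRiskError):
    """Stratification marker has zero variance."""


class ZeroTotal(PCMRiskError):
    """Contribution shares undefined because all scores are zero."""
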