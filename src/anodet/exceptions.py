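"""Exception hierarchy for anodet."""


class AnodetError(Exception):
    """Base class for all anodet errors."""


class InvalidSpecError(AnodetError, ValueError):
    """A generation or configuration spec violates its preconditions."""


class FormatError(AnodetError, ValueError):
    """An image file is missing, unreadable, or not grayscale."""


class ShapeError(AnodetError, ValueError):
    """An array has the wrong shape for the requested operation."""


class StateError(AnodetError, RuntimeError):
    """An operation is invalid in the model's current state."""


class ConfigurationError(AnodetError, ValueError):
    """A training configuration is internally inconsistent."""


class ContractViolationError(AnodetError, ValueError):
    """A dataset contract was violated (e.g. abnormal image in training)."""


class TrainingDivergenceError(AnodetError, RuntimeError):
    """A loss became non-finite during training."""


class UndefinedAurocError(AnodetError, ValueError):
    """ROC analysis attempted with a single class present."""


class InsufficientRepeatsError(AnodetError, ValueError):
    """Cross-validation summary requires at least two repeats."""


class EmptyResultError(AnodetError, ValueError):
    """A ranking or filter produced no records."""
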