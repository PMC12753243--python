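"""Exception hierarchy for mrbodycomp.

Every contract violation raises a subclass of :class:`MRBodyCompError` so
callers can distinguish pipeline failures from programming errors.
"""


class MRBodyCompError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(MRBodyCompError, ValueError):
    """A phantom or training specification violates its invariants."""


class DegenerateAnatomyError(MRBodyCompError):
    """A requested area change would empty (or cannot be realized for) a compartment."""


class OutOfFieldError(MRBodyCompError):
    """A rigid transform would move the body outside the image grid."""


class EmptyROIError(MRBodyCompError, ValueError):
    """An operation requiring a non-empty region received an empty mask."""


class UndefinedMetricError(MRBodyCompError):
    """A surface-distance metric is undefined (an empty mask): a segmentation failure."""


class InsufficientFoldsError(MRBodyCompError, ValueError):
    """Cross-validation summarization requires at least two folds."""


class RegistrationFailureError(MRBodyCompError):
    """Registration similarity stayed below the acceptance floor."""


class UndefinedChangeError(MRBodyCompError, ValueError):
    """Relative change is undefined (non-positive baseline area)."""


class InvalidConfigError(MRBodyCompError, ValueError):
    """A training configuration violates its invariants."""


class TrainingFailureError(MRBodyCompError):
    """Training diverged (non-finite validation metric)."""
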