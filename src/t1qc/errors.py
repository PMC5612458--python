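"""Exception hierarchy.

Every failure mode of the pipeline maps onto one of these so callers
(and the CLI error manifest) can distinguish bad inputs from bad maths.
"""


class T1QCError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(T1QCError, ValueError):
    """A generator or model specification violates its invariants."""


class GeometryError(T1QCError, ValueError):
    """Requested geometry does not fit the image grid."""


class DegenerateArtifactError(T1QCError, ValueError):
    """An artifact operation would be a no-op (e.g. zero-voxel ghost shift)."""


class MaskFailureError(T1QCError, RuntimeError):
    """A mask could not be computed or is implausible (empty, full-FOV)."""


class FitError(T1QCError, RuntimeError):
    """A model fit (bias field, distribution) had too little data or diverged."""


class SegmentationError(T1QCError, RuntimeError):
    """Tissue segmentation degenerated (vanishing component weight)."""


class UndefinedMetricError(T1QCError, ValueError):
    """A quality metric is undefined for this input (zero denominator etc.)."""


class ValidationError(T1QCError, ValueError):
    """A table or label vocabulary failed validation."""


class ContractError(T1QCError, ValueError):
    """Feature-name contract between a fitted model and new data is broken."""
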