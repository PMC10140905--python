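"""Shared exception and warning types."""


class ValidationError(ValueError):
    """Inputs violate a documented precondition."""


class GeometryError(ValidationError):
    """Phantom geometry cannot be placed (e.g. matrix too small)."""


class DegenerateInputError(ValidationError):
    """Statistic undefined for these data (e.g. zero-variance differences)."""


class EmptyRegionError(ValidationError):
    """An ROI has no valid pixels to average over."""


class MuscleNotFoundError(ValidationError):
    """Automatic dorsal-muscle detection failed; supply a manual ROI."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage and acquisition."""


class DegenerateSegmentationWarning(UserWarning):
    """Threshold separated nothing; all kidney pixels fell in one class."""


class EmptyMaskWarning(UserWarning):
    """Background masking left no valid pixels (e.g. all-zero M0)."""
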