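"""Exception and warning types shared across the toolkit."""


class FetalReconError(Exception):
    """Base class for all toolkit errors."""


class InvalidGeometryError(FetalReconError):
    """Degenerate or inconsistent image-grid / slice geometry."""


class EmptyProjectionError(FetalReconError):
    """A slice geometry has no spatial overlap with the volume grid."""


class EmptyInputError(FetalReconError):
    """An operation received no usable input samples."""


class UndefinedSimilarityError(FetalReconError):
    """Similarity is undefined (e.g. constant intensities under the mask)."""


class NoInliersError(FetalReconError):
    """Every slice was rejected; reconstruction cannot proceed.

    Documented recovery: retry with the threshold beta reduced by 0.15.
    """


class NoBrainFoundError(FetalReconError):
    """All stack masks are empty; no target stack can be chosen."""


class RegistrationFailureError(FetalReconError):
    """Rigid registration diverged or the metric is undefined."""


class NoTemplateError(FetalReconError):
    """The template atlas is empty."""


class AlignmentFailureError(FetalReconError):
    """All PBA-initialized template registrations failed."""


class NoDetectionError(FetalReconError):
    """No supra-threshold component survived localization post-processing."""


class CannotDownscaleError(FetalReconError):
    """Probability map too small for another 2x2 average pooling."""


class InvalidScaleCountError(FetalReconError):
    """Requested number of loss scales exceeds the map resolution."""


class InvalidArchitectureError(FetalReconError):
    """Network specification violates the declared architecture contract."""


class UndefinedMetricError(FetalReconError):
    """Metric undefined for the given inputs (e.g. two empty masks)."""


class NoOverlapWarning(UserWarning):
    """Masked regions do not overlap; the operation is a pass-through."""


class AmbiguousAxesWarning(UserWarning):
    """Near-isotropic mask: principal axes are not well determined."""


class DegenerateNormalizationWarning(UserWarning):
    """Zero-variance input to intensity normalization."""
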