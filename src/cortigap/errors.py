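"""Exception hierarchy shared by all pipeline stages."""


class CortigapError(Exception):
    """Base class for all package errors."""


class MetadataError(CortigapError):
    """Voxel-size metadata missing, zero or malformed."""


class UnsupportedGeometryError(CortigapError):
    """Input geometry the pipeline cannot represent (e.g. anisotropic voxels)."""


class GeometryMismatchError(CortigapError):
    """Two volumes that must share a grid do not."""


class EmptyContourError(CortigapError):
    """Auto-contouring found no foreground object."""


class ContourValidationError(CortigapError):
    """A supplied periosteal contour violates its invariants."""


class DegenerateSegmentationWarning(UserWarning):
    """Threshold outside the intensity range: all-bone or all-void result."""


class CalibrationError(CortigapError):
    """BV/TV threshold calibration cannot reach the requested target."""


class ConfigError(CortigapError):
    """Missing or inconsistent configuration value."""


class LabelGapError(CortigapError):
    """Label volume has non-contiguous labels and policy forbids renumbering."""


class DegenerateMaskWarning(UserWarning):
    """Cortical-mask erosion emptied the interior (object too thin)."""


class InternalConsistencyError(CortigapError):
    """An invariant that should hold by construction was violated."""


class UndefinedMetricError(CortigapError):
    """A ratio metric was requested with a zero denominator."""


class PhantomSpecError(CortigapError):
    """Synthetic phantom specification is geometrically invalid."""


class StageError(CortigapError):
    """Pipeline stage failure, wrapping the original error with stage context."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original!r}")
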