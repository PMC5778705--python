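"""Exception hierarchy for cochmetric."""


class CochmetricError(Exception):
    """Base class for all package errors."""


class VolumeFormatError(CochmetricError):
    """Unsupported or malformed image file."""


class DimensionalityError(CochmetricError):
    """Image is not a 3D scalar volume."""


class FiducialParseError(CochmetricError):
    """Malformed fiducial file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class MissingLabelError(CochmetricError, KeyError):
    """A required fiducial label is absent."""


class EmptyRegionError(CochmetricError):
    """ROI does not intersect the volume."""


class DegenerateMetricError(CochmetricError):
    """Similarity metric undefined (e.g. zero intensity variance)."""


class InsufficientOverlapError(CochmetricError):
    """Too few sample points map inside the target image."""


class DegenerateLandmarksError(CochmetricError):
    """Fewer than 3 usable landmarks, or landmarks collinear."""


class OutOfDomainError(CochmetricError):
    """Point outside a B-spline transform's full-support region."""


class ConfigurationError(CochmetricError):
    """Invalid registration or pipeline configuration."""
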