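"""Exception hierarchy shared across the package."""


class ShoulderSimError(Exception):
    """Base class for all package-specific errors."""


class MetadataError(ShoulderSimError):
    """Inconsistent or missing image metadata (spacing, orientation, tags)."""


class GeometryError(ShoulderSimError):
    """Invalid projection geometry or a phantom body outside the grid."""


class SegmentationError(ShoulderSimError):
    """Background/body separation failed (e.g. constant input volume)."""


class NormalizationError(ShoulderSimError):
    """Degenerate intensity window (low percentile equals high)."""


class ShapeError(ShoulderSimError):
    """Array shape mismatch between volume and mask."""


class MeasurementError(ShoulderSimError):
    """Missing or degenerate landmarks for a morphometric measurement."""


class ValidationError(ShoulderSimError):
    """An ordinal code outside its permitted range."""


class ParameterError(ShoulderSimError):
    """A numeric parameter outside its valid domain."""


class SampleSizeError(ShoulderSimError):
    """Too few observations for the requested statistic."""
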