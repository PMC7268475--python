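"""Exception and warning types shared across the pipeline."""


class UasYieldError(Exception):
    """Base class for all pipeline errors."""


class LayoutError(UasYieldError):
    """Invalid or overlapping plot layout."""


class ParameterError(UasYieldError):
    """Invalid parameter value."""


class EmptyClipError(UasYieldError):
    """A clip produced no pixels (polygon does not intersect the raster)."""


class SampleSizeError(UasYieldError):
    """Too few observations for the requested statistic."""


class DegenerateClusteringError(UasYieldError):
    """Clustering on a constant (or effectively constant) sample."""


class NumericDomainError(UasYieldError):
    """Input outside the numeric domain of a formula (e.g. zero denominator)."""


class IntegrityError(UasYieldError):
    """Duplicate keys or inconsistent inputs when joining feature sources."""


class SplitError(UasYieldError):
    """Train/test split cannot be formed."""


class MeshingError(UasYieldError):
    """Degenerate geometry prevents triangulation."""


class CalibrationError(UasYieldError):
    """Bar residual above tolerance after height calibration."""


class FitError(UasYieldError):
    """Degenerate regression input."""


class DegreesOfFreedomError(UasYieldError):
    """Not enough observations for leave-one-out studentization."""


class RegistrationWarning(UserWarning):
    """ICP did not improve on its initial alignment."""


class DataQualityWarning(UserWarning):
    """More points filtered than the configured maximum fraction."""
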