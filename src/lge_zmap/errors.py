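"""Exception hierarchy for the lge-zmap pipeline.

Each pipeline stage raises a dedicated subclass so that the driver can
abort with stage-tagged diagnostics and the CLI can map failures to exit
codes (2 = schema/input error, 3 = statistical failure).
"""


class LgeZmapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LgeZmapError):
    """Invalid or non-finite configuration values."""


class SchemaError(LgeZmapError):
    """A table or file violates the expected schema."""


class ConsistencyError(SchemaError):
    """Stored wall/band labels contradict the segment/layer maps."""


class GeometryError(LgeZmapError):
    """Degenerate or invalid contour geometry."""


class AlignmentError(GeometryError):
    """Image stack and contour stack do not line up."""


class EmptyRegionError(LgeZmapError):
    """A requested region contains no usable (non-excluded) cells."""


class InsufficientDataError(LgeZmapError):
    """Too few observations for the requested statistic."""


class DegenerateVarianceError(InsufficientDataError):
    """Zero intensity variance: z-scores are undefined."""


class StratificationError(LgeZmapError):
    """A class has fewer members than the number of CV folds."""


class UndefinedValueError(LgeZmapError):
    """A ratio with zero denominator (e.g. PPV at prevalence 0)."""


class StageError(LgeZmapError):
    """Wraps a stage failure inside the pipeline driver."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
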