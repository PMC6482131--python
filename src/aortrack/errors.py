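"""Exception hierarchy for the aortrack pipeline.

Every stage raises a subclass of :class:`AortrackError` so the pipeline
driver can halt with the stage name and a human-readable reason, leaving
completed intermediates on disk for manual inspection.
"""


class AortrackError(Exception):
    """Base class for all aortrack errors."""


class FormatError(AortrackError):
    """Unreadable or unsupported image file / extension."""


class AmbiguousSeriesError(FormatError):
    """A DICOM directory contains more than one series."""

    def __init__(self, series_ids):
        self.series_ids = list(series_ids)
        super().__init__(
            f"directory contains {len(self.series_ids)} DICOM series: "
            + ", ".join(self.series_ids)
        )


class GeometryError(AortrackError):
    """Geometric precondition violated (tube exits grid, degenerate polygon...)."""


class OutOfRangeError(GeometryError):
    """A measurement plane does not intersect the surface."""


class BoundaryIntersectionError(GeometryError):
    """A measurement plane crosses an open boundary ring of the tube."""


class ExtractionFailure(AortrackError):
    """Centerline extraction failed (no admissible path / endpoints)."""


class EndpointDetectionError(ExtractionFailure):
    """Automatic endpoint detection found no admissible component."""


class FitFailure(AortrackError):
    """Deformable surface fit left the volume or failed a validity check."""


class RegistrationFailure(AortrackError):
    """Image registration could not proceed (insufficient overlap...)."""


class InsufficientOverlapError(RegistrationFailure):
    """Fewer than half of the metric samples map inside the moving image."""


class AnnotationError(AortrackError):
    """A landmark annotation is too far from the centerline."""


class SchemaError(AortrackError):
    """Invalid landmark vocabulary, config keys, or report structure."""


class PipelineError(AortrackError):
    """A pipeline stage failed; carries the stage name and intermediates."""

    def __init__(self, stage, reason, intermediates=None):
        self.stage = stage
        self.reason = reason
        self.intermediates = dict(intermediates or {})
        msg = f"pipeline halted at stage '{stage}': {reason}"
        if self.intermediates:
            msg += "; completed intermediates: " + ", ".join(
                f"{k}={v}" for k, v in self.intermediates.items()
            )
        super().__init__(msg)
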