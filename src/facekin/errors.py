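"""Exception hierarchy.

Every failure mode of the pipeline maps onto one of these so that the
orchestrator can distinguish "this token is bad" (skip and log) from
"the caller misused the API" (raise through).
"""


class FacekinError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(FacekinError, ValueError):
    """A precondition on an argument was violated."""


class InvalidStateError(FacekinError, RuntimeError):
    """Operation applied to an object in the wrong state (e.g. double
    head-motion compensation, double unit conversion)."""


class DetectionFailureError(FacekinError):
    """A cascade/box detector exhausted its merge-threshold schedule
    without producing a unique bounding box."""

    def __init__(self, kind: str, message: str | None = None):
        self.kind = kind
        super().__init__(message or f"detection failed for region kind {kind!r}")


class SegmentationFailureError(FacekinError):
    """An active-contour or mask-based segmentation collapsed or came
    back empty."""


class TrackingFailureError(FacekinError):
    """All keypoints were lost before tracking could begin."""


class DegenerateGeometryError(FacekinError):
    """Geometric construction is undefined (e.g. nose tip lying on the
    inter-eye line gives a zero head-size normalizer)."""


class PipelineFailureError(FacekinError):
    """Every token in a run failed."""
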