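"""Exception hierarchy.

Every failure mode of the pipeline surfaces as a :class:`PhotoscreenError`
subclass carrying the name of the stage that failed, so batch runs can record
structured per-case failures without aborting.
"""

from __future__ import annotations


class PhotoscreenError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PhotoscreenError, ValueError):
    """An input (scene spec, landmark record, config) violated an invariant.

    The message names the offending field.
    """


class DetectionError(PhotoscreenError):
    """An image operator failed to find its structure (limbus, CLR, QR...)."""

    def __init__(self, message: str, stage: str = ""):
        super().__init__(message)
        self.stage = stage


class ClosedEyeError(DetectionError):
    """An eye was rejected as closed by the openness gate."""

    def __init__(self, eye: str, ratio: float, eta: float):
        super().__init__(
            f"{eye} eye rejected as closed: openness ratio "
            f"{ratio:.3f} < eta={eta}",
            stage="eye_openness",
        )
        self.eye = eye
        self.ratio = ratio
        self.eta = eta


class ScaleDecodeError(DetectionError):
    """The QR scale fiducial could not be decoded."""

    def __init__(self, message: str):
        super().__init__(message, stage="decode_scale")


class MetricUndefinedError(PhotoscreenError):
    """A confusion-matrix metric has a zero denominator."""

    def __init__(self, metric: str):
        super().__init__(f"metric '{metric}' is undefined (zero denominator)")
        self.metric = metric
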