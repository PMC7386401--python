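"""Optics and decision layer for the photoscreening exam.

The automated Hirschberg test reduces ocular alignment to the pixel offset
(dx, dy) of the corneal-light-reflection (CLR) spot from the limbus center.
With a frontal-plane scale of ``alpha`` mm/px and an assumed eyeball
diameter ``d`` (20 mm, population average — the quantity is not measurable
in a photo), the axial deviation of one eye from the camera/flash axis is

    theta = atan(2 * alpha * dx / d)

per axis.  The binocular deviations are the left-minus-right differences;
a clearly positive horizontal difference indicates exotropia, a clearly
negative one esotropia, and a nonzero vertical difference indicates
vertical strabismus.

Photorefraction contributes per-eye red-reflex crescent widths (mm): a
crescent on the flash side of the pupil indicates myopia, on the far side
hyperopia, and a fully lit pupil leaves the direction indeterminate.

Risk flags are pure threshold functions of these measurements; the default
cutoffs are a 10 degree relative visual angle for strabismus, a 1 mm
crescent for refractive error, and a 1 mm inter-eye width difference for
anisometropia.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import MetricUndefinedError, ValidationError

TOWARD_FLASH = "toward-flash"
AWAY_FROM_FLASH = "away-from-flash"
NO_CRESCENT = "none"


@dataclass(frozen=True)
class ScreeningConfig:
    """Thresholds and geometry assumptions of the screening exam.

    Parameters
    ----------
    d_mm:
        Assumed eyeball diameter in mm (not measurable from the image).
    strabismus_deg:
        Minimum binocular deviation (deg, either axis) flagged as strabismus.
    crescent_mm:
        Minimum crescent width (mm) flagged as refractive-error risk.
    aniso_mm:
        Minimum inter-eye crescent width difference (mm) flagged as
        anisometropia.
    eta:
        Eye-openness (height/width) ratio below which an eye counts as closed.
    flash_side:
        Side of the camera the flash sits on, from the examiner's view
        ("left" or "right"); fixes the myopia/hyperopia crescent semantics.
    """

    d_mm: float = 20.0
    strabismus_deg: float = 10.0
    crescent_mm: float = 1.0
    aniso_mm: float = 1.0
    eta: float = 0.25
    flash_side: str = "left"

    def __post_init__(self):
        for name in ("d_mm", "strabismus_deg", "crescent_mm", "aniso_mm", "eta"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if self.flash_side not in ("left", "right"):
            raise ValidationError("flash_side must be 'left' or 'right'")

    @classmethod
    def from_yaml(cls, path) -> "ScreeningConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class EyeOffsets:
    """CLR-minus-limbus center offsets in pixels (x right, y down)."""

    dx_left: float
    dy_left: float
    dx_right: float
    dy_right: float

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if not math.isfinite(getattr(self, f.name)):
                raise ValidationError(f"{f.name} must be finite")


@dataclass(frozen=True)
class GazeDeviation:
    """Per-eye and binocular axial deviations in degrees."""

    horizontal_left: float
    horizontal_right: float
    vertical_left: float
    vertical_right: float

    @property
    def horizontal(self) -> float:
        return self.horizontal_left - self.horizontal_right

    @property
    def vertical(self) -> float:
        return self.vertical_left - self.vertical_right

    def to_dict(self) -> dict:
        return {
            "horizontal_left": self.horizontal_left,
            "horizontal_right": self.horizontal_right,
            "vertical_left": self.vertical_left,
            "vertical_right": self.vertical_right,
            "horizontal": self.horizontal,
            "vertical": self.vertical,
        }


def axial_deviation(delta_px, alpha_mm_per_px: float, d_mm: float = 20.0):
    """Axial deviation (deg) of one eye: atan(2 * alpha * delta / d).

    Odd and monotone increasing in ``delta_px``; accepts scalars or arrays.
    """
    if not (math.isfinite(alpha_mm_per_px) and alpha_mm_per_px > 0):
        raise ValidationError("alpha_mm_per_px must be finite and > 0")
    if not (math.isfinite(d_mm) and d_mm > 0):
        raise ValidationError("d_mm must be finite and > 0")
    delta = np.asarray(delta_px, dtype=float)
    if not np.all(np.isfinite(delta)):
        raise ValidationError("delta_px must be finite")
    theta = np.degrees(np.arctan(2.0 * alpha_mm_per_px * delta / d_mm))
    return float(theta) if np.isscalar(delta_px) else theta


def binocular_deviation(offsets: EyeOffsets, alpha_mm_per_px: float,
                        d_mm: float = 20.0) -> GazeDeviation:
    """Per-eye axial deviations and their left-minus-right differences."""
    return GazeDeviation(
        horizontal_left=axial_deviation(offsets.dx_left, alpha_mm_per_px, d_mm),
        horizontal_right=axial_deviation(offsets.dx_right, alpha_mm_per_px, d_mm),
        vertical_left=axial_deviation(offsets.dy_left, alpha_mm_per_px, d_mm),
        vertical_right=axial_deviation(offsets.dy_right, alpha_mm_per_px, d_mm),
    )


def interpupillary_distance(center_left, center_right,
                            alpha_mm_per_px: float) -> float:
    """IPD in mm: scale times the distance between limbus centers.

    Centers are (x, y) in tilt-corrected image coordinates.
    """
    if not alpha_mm_per_px > 0:
        raise ValidationError("alpha_mm_per_px must be > 0")
    left = np.asarray(center_left, dtype=float)
    right = np.asarray(center_right, dtype=float)
    dist = float(np.linalg.norm(left - right))
    if dist == 0:
        raise ValidationError("limbus centers coincide; IPD undefined")
    return alpha_mm_per_px * dist


MYOPIC = "myopic"
HYPEROPIC = "hyperopic"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class RiskFlags:
    """Screening outcome: risk flags derived from the measurements."""

    strabismus: bool
    refractive_left: bool
    refractive_right: bool
    direction_left: str | None  # myopic | hyperopic | indeterminate | None
    direction_right: str | None
    anisometropia: bool

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def classify(gaze: GazeDeviation, crescent_left, crescent_right,
             config: ScreeningConfig = ScreeningConfig()) -> RiskFlags:
    """Threshold the measurements into risk flags.

    ``crescent_left`` / ``crescent_right`` need attributes ``width_mm``,
    ``side`` (toward-flash / away-from-flash / none) and ``full_pupil``
    (e.g. :class:`photoscreen.segment.Crescent`).

    Strabismus risk uses the larger of the two binocular axes; refractive
    risk is per eye on the crescent width, with the direction read from the
    crescent side (indeterminate when the whole pupil lights up, as severe
    myopia and hyperopia are then indistinguishable); anisometropia uses the
    unsigned width difference.
    """
    for name, c in (("left", crescent_left), ("right", crescent_right)):
        if c is None:
            raise ValidationError(f"missing crescent measurement for {name} eye")

    strab = max(abs(gaze.horizontal), abs(gaze.vertical)) >= config.strabismus_deg

    def eye_flags(crescent):
        risk = crescent.width_mm >= config.crescent_mm
        if not risk:
            return False, None
        if crescent.full_pupil:
            return True, INDETERMINATE
        if crescent.side == TOWARD_FLASH:
            return True, MYOPIC
        if crescent.side == AWAY_FROM_FLASH:
            return True, HYPEROPIC
        return True, INDETERMINATE

    risk_l, dir_l = eye_flags(crescent_left)
    risk_r, dir_r = eye_flags(crescent_right)
    aniso = abs(crescent_left.width_mm - crescent_right.width_mm) >= config.aniso_mm
    return RiskFlags(
        strabismus=bool(strab),
        refractive_left=bool(risk_l),
        refractive_right=bool(risk_r),
        direction_left=dir_l,
        direction_right=dir_r,
        anisometropia=bool(aniso),
    )


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValidationError(f"{f.name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def confusion_metrics(cm: ConfusionMatrix) -> Metrics:
    """Accuracy, sensitivity and specificity from raw counts.

    accuracy = (TP+TN)/(TP+TN+FP+FN), sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP); a zero denominator raises
    :class:`MetricUndefinedError` naming the metric.
    """
    if cm.total == 0:
        raise MetricUndefinedError("accuracy")
    if cm.tp + cm.fn == 0:
        raise MetricUndefinedError("sensitivity")
    if cm.tn + cm.fp == 0:
        raise MetricUndefinedError("specificity")
    return Metrics(
        accuracy=(cm.tp + cm.tn) / cm.total,
        sensitivity=cm.tp / (cm.tp + cm.fn),
        specificity=cm.tn / (cm.tn + cm.fp),
    )


@dataclass
class ScreeningResult:
    """Full per-examinee screening report."""

    examinee_id: str
    gaze: GazeDeviation
    crescent_width_left_mm: float
    crescent_width_right_mm: float
    crescent_side_left: str
    crescent_side_right: str
    ipd_mm: float
    flags: RiskFlags
    attempt_index: int = 0
    quality_notes: list[str] = field(default_factory=list)
    trace: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "examinee_id": self.examinee_id,
            "gaze_deg": self.gaze.to_dict(),
            "crescent_width_left_mm": self.crescent_width_left_mm,
            "crescent_width_right_mm": self.crescent_width_right_mm,
            "crescent_side_left": self.crescent_side_left,
            "crescent_side_right": self.crescent_side_right,
            "ipd_mm": self.ipd_mm,
            "flags": self.flags.to_dict(),
            "attempt_index": self.attempt_index,
            "quality_notes": list(self.quality_notes),
            "trace": self.trace,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)
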