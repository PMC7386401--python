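"""Facial-landmark ingestion, closed-eye rejection, tilt correction and
eye-patch extraction.

Landmark detection itself (a deep face model in the capture app) is out of
scope; this module consumes its output as a JSON record — per-eye corner
points, eyelid contour points, and the head-tilt angle — validates it, and
prepares per-eye image patches for the hard-coded segmentation operators.

Eyes whose lid aperture is too small relative to their width (a blink) are
rejected before any image processing: the openness ratio is the maximum
vertical gap between the upper and lower lid contours divided by the
corner distance, and an eye counts as closed strictly below the threshold
eta (default 0.25).

"left"/"right" are anatomical (the examinee's left eye appears on the
right half of a frontal photo).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import AffineTransform, warp

from .errors import ClosedEyeError, ValidationError
from .geometry import affine_about

DEFAULT_ETA = 0.25
PATCH_PAD_FRAC = 0.25  # padding per side, as a fraction of corner distance


@dataclass(frozen=True)
class EyeLandmarks:
    """Landmark points of one eye (original-image px coordinates)."""

    inner_corner: np.ndarray  # (2,)
    outer_corner: np.ndarray
    upper_lid: np.ndarray  # (N, 2), N >= 3
    lower_lid: np.ndarray

    @property
    def corner_distance(self) -> float:
        return float(np.linalg.norm(self.inner_corner - self.outer_corner))

    @property
    def centroid(self) -> np.ndarray:
        return (self.inner_corner + self.outer_corner) / 2.0


@dataclass(frozen=True)
class FaceLandmarks:
    left: EyeLandmarks
    right: EyeLandmarks
    head_tilt_deg: float
    image_size: tuple[int, int]  # (width, height)
    source: str = "external-detector"


def _as_points(value, name: str, min_points: int = 1) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < min_points:
        raise ValidationError(
            f"{name} must be at least {min_points} (x, y) point(s)"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite coordinates")
    return arr


def load_landmarks(record) -> FaceLandmarks:
    """Parse and validate a landmark record (path, JSON text, or dict).

    Schema::

        {"image_size": [w, h], "head_tilt_deg": t, "source": "...",
         "eyes": {"left":  {"inner_corner": [x, y], "outer_corner": [x, y],
                            "upper_lid": [[x, y], ...], "lower_lid": [...]},
                  "right": {...}}}
    """
    if isinstance(record, (str, Path)) and not str(record).lstrip().startswith("{"):
        with open(record) as fh:
            data = json.load(fh)
    elif isinstance(record, str):
        data = json.loads(record)
    else:
        data = record
    if not isinstance(data, dict) or "eyes" not in data:
        raise ValidationError("landmark record missing 'eyes'")
    try:
        w, h = data["image_size"]
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError("landmark record missing image_size [w, h]") from exc

    eyes = {}
    for name in ("left", "right"):
        if name not in data["eyes"]:
            raise ValidationError(f"landmark record missing '{name}' eye")
        e = data["eyes"][name]
        for key in ("inner_corner", "outer_corner", "upper_lid", "lower_lid"):
            if key not in e:
                raise ValidationError(f"{name} eye missing '{key}'")
        eye = EyeLandmarks(
            inner_corner=_as_points(e["inner_corner"], f"{name}.inner_corner")[0],
            outer_corner=_as_points(e["outer_corner"], f"{name}.outer_corner")[0],
            upper_lid=_as_points(e["upper_lid"], f"{name}.upper_lid", 3),
            lower_lid=_as_points(e["lower_lid"], f"{name}.lower_lid", 3),
        )
        if eye.corner_distance <= 0:
            raise ValidationError(f"{name} eye corner distance must be > 0")
        allpts = np.vstack([eye.inner_corner, eye.outer_corner,
                            eye.upper_lid, eye.lower_lid])
        if (allpts[:, 0].min() < -0.5 or allpts[:, 1].min() < -0.5
                or allpts[:, 0].max() > w - 0.5 or allpts[:, 1].max() > h - 0.5):
            raise ValidationError(f"{name} eye has points outside image bounds")
        eyes[name] = eye
    return FaceLandmarks(
        left=eyes["left"], right=eyes["right"],
        head_tilt_deg=float(data.get("head_tilt_deg", 0.0)),
        image_size=(int(w), int(h)),
        source=str(data.get("source", "external-detector")),
    )


def eye_openness(eye: EyeLandmarks, eta: float = DEFAULT_ETA):
    """Height-to-width openness ratio and the closed flag.

    The ratio is the maximum vertical gap between the lid contours
    (linearly interpolated over their common x-range) divided by the corner
    distance; scale-invariant by construction.  ``closed`` uses a strict
    comparison, so a ratio exactly at eta still passes.
    """
    cd = eye.corner_distance
    if cd <= 0:
        raise ValidationError("corner distance must be > 0")
    up = eye.upper_lid[np.argsort(eye.upper_lid[:, 0])]
    lo = eye.lower_lid[np.argsort(eye.lower_lid[:, 0])]
    x_lo = max(up[0, 0], lo[0, 0])
    x_hi = min(up[-1, 0], lo[-1, 0])
    if x_hi <= x_lo:
        gap = 0.0
    else:
        xs = np.unique(np.concatenate([
            up[:, 0], lo[:, 0], np.linspace(x_lo, x_hi, 17)
        ]))
        xs = xs[(xs >= x_lo) & (xs <= x_hi)]
        gap = float(np.max(np.maximum(
            np.interp(xs, lo[:, 0], lo[:, 1]) - np.interp(xs, up[:, 0], up[:, 1]),
            0.0,
        )))
    ratio = gap / cd
    return ratio, ratio < eta


@dataclass
class EyePatch:
    """A per-eye crop of the tilt-corrected image.

    ``origin`` is the patch's top-left corner in corrected-image
    coordinates, so a patch point p maps to corrected coordinates
    ``p + origin`` (and through the recorded rotation back to the original
    image).
    """

    pixels: np.ndarray  # (H, W, 3) uint8
    origin: tuple[int, int]  # (x0, y0), corrected-image coordinates
    rotation_deg: float  # rotation applied to the original image (-tilt)
    pivot: tuple[float, float]
    eye: str  # "left" | "right" (anatomical)
    corner_distance: float

    def to_corrected(self, points) -> np.ndarray:
        return np.atleast_2d(np.asarray(points, dtype=float)) + np.asarray(self.origin)

    def from_corrected(self, points) -> np.ndarray:
        return np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.origin)


def _rotated_image(image: np.ndarray, tilt_deg: float, pivot) -> np.ndarray:
    if tilt_deg == 0:
        return np.asarray(image)
    # warp wants the output->input map; rotating the content by -tilt means
    # sampling the input at +tilt
    tform = AffineTransform(matrix=affine_about(tilt_deg, pivot))
    out = warp(np.asarray(image, dtype=np.float64), tform, order=1,
               preserve_range=True, cval=0.0)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def extract_eye_patches(image: np.ndarray, landmarks: FaceLandmarks,
                        eta: float = DEFAULT_ETA,
                        pad_frac: float = PATCH_PAD_FRAC):
    """Tilt-correct the image and crop one patch per eye.

    The image is rotated by minus the head tilt about the midpoint between
    the two eye-corner centroids (bilinear interpolation), leveling the
    eyes; each patch covers the eye-corner span and the lid-point span
    padded by ``pad_frac`` of the corner distance on every side.  Closed
    eyes raise :class:`ClosedEyeError` carrying the openness ratio; a patch
    clipped by the image border raises :class:`ValidationError`.

    Returns ``(left_patch, right_patch)`` (anatomical labels).
    """
    for name in ("left", "right"):
        eye = getattr(landmarks, name)
        ratio, closed = eye_openness(eye, eta)
        if closed:
            raise ClosedEyeError(name, ratio, eta)

    pivot = (landmarks.left.centroid + landmarks.right.centroid) / 2.0
    tilt = landmarks.head_tilt_deg
    corrected = _rotated_image(image, tilt, pivot)
    rot = affine_about(-tilt, pivot)

    def correct(points):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ rot[:2, :2].T + rot[:2, 2]

    patches = {}
    h, w = corrected.shape[:2]
    for name in ("left", "right"):
        eye = getattr(landmarks, name)
        cd = eye.corner_distance
        pts = correct(np.vstack([
            eye.inner_corner, eye.outer_corner, eye.upper_lid, eye.lower_lid
        ]))
        pad = pad_frac * cd
        x0 = int(np.floor(pts[:, 0].min() - pad))
        x1 = int(np.ceil(pts[:, 0].max() + pad)) + 1
        y0 = int(np.floor(pts[:, 1].min() - pad))
        y1 = int(np.ceil(pts[:, 1].max() + pad)) + 1
        if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
            raise ValidationError(
                f"{name} eye patch [{x0}:{x1}, {y0}:{y1}] is clipped by the "
                f"image border ({w}x{h})"
            )
        patches[name] = EyePatch(
            pixels=corrected[y0:y1, x0:x1],
            origin=(x0, y0),
            rotation_deg=-tilt,
            pivot=(float(pivot[0]), float(pivot[1])),
            eye=name,
            corner_distance=cd,
        )
    return patches["left"], patches["right"]
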