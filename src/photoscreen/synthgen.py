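"""Synthetic two-image exam scenes with exact ground truth.

Each rendered examinee is a pair of frontal face images sharing one
geometry:

* a **Hirschberg still** — contracted pupil, bright specular CLR spot at a
  controllable offset from the limbus center, no red reflex;
* a **red-reflex frame** — dilated pupil, a red crescent of controllable
  width rising from a controllable side of the pupil, CLR spot present.

Scenes are drawn analytically (flat-shaded disks, half-plane lid and
crescent cuts, anti-aliased edges) directly in the tilted head frame, so no
resampling touches the ground truth: eye geometry is specified in the
tilt-corrected ("canonical") frame and every pixel is evaluated through the
exact inverse rotation.  A QR fiducial of known physical edge length is
embedded upright near the top of the frame, exactly as a phone held at the
forehead would appear.

Ground truth (:class:`SceneTruth`) carries the scale, the per-eye CLR
offsets and their closed-form deviation angles, crescent widths/sides, the
landmark record, and condition labels obtained by running the screening
classifier on the noise-free measurements — so end-to-end recovery on
clean scenes must be perfect by construction.

What this emulates — and what it does not: the renderer reproduces the
geometry and photometric contrasts the downstream operators key on
(sclera/iris boundary, skin hue/saturation, specular spot, red crescent,
eyelid occlusion, head tilt, sensor noise), not photorealistic eyes, fundus
reflectance, or video.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import qr, screen
from .errors import ValidationError
from .geometry import rotation_matrix

CLR_RADIUS_FRAC = 0.08  # CLR spot radius as a fraction of the limbus radius
HIRSCHBERG_PUPIL_FRAC = 0.5  # pupil contraction in the flash still

PUPIL_RGB = (12, 10, 10)
CRESCENT_RGB = (250, 60, 50)
CLR_RGB = (252, 252, 252)
DEFAULT_SKIN_RGB = (214, 160, 120)
DEFAULT_SCLERA_RGB = (242, 240, 238)
DEFAULT_IRIS_RGB = (32, 30, 29)

# palpebral-fissure (eye opening) ellipse semi-axes, in limbus radii
OPEN_A_FRAC = 2.0
OPEN_B_FRAC = 1.3


@dataclass(frozen=True)
class EyeSpec:
    """One eye of a scene, in canonical (tilt-corrected) coordinates."""

    center: tuple[float, float]  # limbus center, px
    limbus_radius: float  # px
    pupil_radius: float  # px, dilated (red-reflex) pupil
    clr_offset: tuple[float, float] = (0.0, 0.0)  # (dx, dy) px
    crescent_width_mm: float = 0.0
    crescent_side: str = screen.TOWARD_FLASH
    lid_occlusion_deg: tuple[float, float] = (0.0, 0.0)  # (top, bottom)


@dataclass(frozen=True)
class EyeSceneSpec:
    """Parametric description of a rendered two-image exam scene."""

    width: int = 1024
    height: int = 704
    left: EyeSpec = field(default_factory=lambda: EyeSpec((802.0, 530.0), 55.0, 33.0))
    right: EyeSpec = field(default_factory=lambda: EyeSpec((222.0, 530.0), 55.0, 33.0))
    skin_rgb: tuple[int, int, int] = DEFAULT_SKIN_RGB
    sclera_rgb: tuple[int, int, int] = DEFAULT_SCLERA_RGB
    iris_rgb: tuple[int, int, int] = DEFAULT_IRIS_RGB
    head_tilt_deg: float = 0.0
    pixels_per_mm: float = 10.0
    noise_sigma: float = 0.0
    seed: int = 0
    flash_side: str = "left"  # examiner's view; fixes crescent laterality
    embed_qr: bool = True
    qr_payload_id: str = "anon"
    qr_edge_mm: float = 26.0

    def validate(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValidationError("width/height must be at least 64 px")
        if not self.pixels_per_mm > 0:
            raise ValidationError("pixels_per_mm must be > 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.flash_side not in ("left", "right"):
            raise ValidationError("flash_side must be 'left' or 'right'")
        for name, eye in (("left", self.left), ("right", self.right)):
            if not eye.limbus_radius > eye.pupil_radius > 0:
                raise ValidationError(
                    f"{name}.limbus_radius > pupil_radius > 0 violated"
                )
            if eye.crescent_width_mm < 0:
                raise ValidationError(f"{name}.crescent_width_mm must be >= 0")
            if eye.crescent_width_mm * self.pixels_per_mm >= 2 * eye.pupil_radius:
                raise ValidationError(
                    f"{name}.crescent_width_mm exceeds the pupil diameter"
                )
            if eye.crescent_side not in (screen.TOWARD_FLASH, screen.AWAY_FROM_FLASH):
                raise ValidationError(f"{name}.crescent_side invalid")
            for lid in eye.lid_occlusion_deg:
                if not 0.0 <= lid < 90.0:
                    raise ValidationError(
                        f"{name}.lid_occlusion_deg must be in [0, 90)"
                    )

    @property
    def pivot(self) -> np.ndarray:
        """Rotation pivot: midpoint of the two eye centers (canonical)."""
        return (np.asarray(self.left.center) + np.asarray(self.right.center)) / 2.0


@dataclass
class SceneTruth:
    """Exact ground truth of a rendered scene."""

    alpha_mm_per_px: float
    offsets: screen.EyeOffsets  # CLR-minus-limbus, canonical frame, px
    gaze: screen.GazeDeviation  # closed-form deviation angles, deg
    crescent_width_left_mm: float
    crescent_width_right_mm: float
    crescent_side_left: str
    crescent_side_right: str
    limbus_center_left: tuple[float, float]  # canonical frame
    limbus_center_right: tuple[float, float]
    limbus_radius_left: float
    limbus_radius_right: float
    ipd_mm: float
    head_tilt_deg: float
    landmarks: dict  # landmark record, original-frame coordinates
    labels: dict  # condition booleans from the classifier on the truth

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["offsets"] = dataclasses.asdict(self.offsets)
        d["gaze"] = self.gaze.to_dict()
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


# ----------------------------------------------------------------------------
# Analytic rendering
# ----------------------------------------------------------------------------


def _paint(img: np.ndarray, alpha: np.ndarray, rgb) -> None:
    img *= (1.0 - alpha)[..., None]
    img += alpha[..., None] * np.asarray(rgb, dtype=np.float64)


def _disk_alpha(xc, yc, cx, cy, r):
    d = np.hypot(xc - cx, yc - cy) - r
    return np.clip(0.5 - d, 0.0, 1.0)


def _render_eye(img, xc_full, yc_full, eye: EyeSpec, spec: EyeSceneSpec,
                pupil_radius: float, crescent: bool) -> None:
    cx, cy = eye.center
    R = eye.limbus_radius
    # paint only a window around the eye (its original-frame footprint)
    corners = _to_original(np.array([
        [cx - OPEN_A_FRAC * R, cy - OPEN_B_FRAC * R],
        [cx + OPEN_A_FRAC * R, cy - OPEN_B_FRAC * R],
        [cx - OPEN_A_FRAC * R, cy + OPEN_B_FRAC * R],
        [cx + OPEN_A_FRAC * R, cy + OPEN_B_FRAC * R],
    ]), spec)
    x0 = max(0, int(corners[:, 0].min()) - 2)
    x1 = min(img.shape[1], int(np.ceil(corners[:, 0].max())) + 3)
    y0 = max(0, int(corners[:, 1].min()) - 2)
    y1 = min(img.shape[0], int(np.ceil(corners[:, 1].max())) + 3)
    img = img[y0:y1, x0:x1]
    xc = xc_full[y0:y1, x0:x1]
    yc = yc_full[y0:y1, x0:x1]
    a, b = OPEN_A_FRAC * R, OPEN_B_FRAC * R
    # palpebral fissure (sclera background)
    val = ((xc - cx) / a) ** 2 + ((yc - cy) / b) ** 2
    open_alpha = np.clip((1.0 - val) * b, 0.0, 1.0)
    _paint(img, open_alpha, spec.sclera_rgb)
    # iris disk (its rim is the limbus)
    iris = _disk_alpha(xc, yc, cx, cy, R) * open_alpha
    _paint(img, iris, spec.iris_rgb)
    # pupil
    pupil = _disk_alpha(xc, yc, cx, cy, pupil_radius) * open_alpha
    _paint(img, pupil, PUPIL_RGB)
    # red-reflex crescent: hard cut in canonical x so the rendered width is
    # exact; soft only along the pupil rim.  A reflex flooding most of the
    # pupil (severe refractive error) is rendered with a saturated red
    # channel, as an intense fundus glow overexposes the sensor.
    w_px = eye.crescent_width_mm * spec.pixels_per_mm
    if crescent and w_px > 0:
        flash_left = spec.flash_side == "left"
        toward = eye.crescent_side == screen.TOWARD_FLASH
        on_left = toward == flash_left
        if on_left:
            cut = xc <= cx - pupil_radius + w_px
        else:
            cut = xc >= cx + pupil_radius - w_px
        d = np.clip((pupil_radius - w_px) / pupil_radius, -1.0, 1.0)
        seg_frac = (np.arccos(d) - d * np.sqrt(1 - d * d)) / np.pi
        color = (255, 70, 55) if seg_frac > 0.5 else CRESCENT_RGB
        _paint(img, pupil * cut, color)
    # CLR spot
    sx, sy = cx + eye.clr_offset[0], cy + eye.clr_offset[1]
    spot = _disk_alpha(xc, yc, sx, sy, CLR_RADIUS_FRAC * R) * open_alpha
    _paint(img, spot, CLR_RGB)
    # eyelids: skin-colored half-plane overlays covering the top/bottom
    # limbus arcs beyond the occlusion half-angle
    top, bottom = eye.lid_occlusion_deg
    if top > 0:
        chord = cy - R * np.cos(np.deg2rad(top))
        lid = open_alpha * np.clip(chord - yc + 0.5, 0.0, 1.0)
        _paint(img, lid, spec.skin_rgb)
    if bottom > 0:
        chord = cy + R * np.cos(np.deg2rad(bottom))
        lid = open_alpha * np.clip(yc - chord + 0.5, 0.0, 1.0)
        _paint(img, lid, spec.skin_rgb)


def _canonical_grid(spec: EyeSceneSpec):
    """Canonical (tilt-corrected) coordinates of every original pixel."""
    yy, xx = np.mgrid[0:spec.height, 0:spec.width].astype(np.float64)
    px, py = spec.pivot
    minv = rotation_matrix(-spec.head_tilt_deg)
    xc = px + minv[0, 0] * (xx - px) + minv[0, 1] * (yy - py)
    yc = py + minv[1, 0] * (xx - px) + minv[1, 1] * (yy - py)
    return xc, yc


def _embed_qr(img: np.ndarray, spec: EyeSceneSpec) -> None:
    payload = json.dumps(
        {"id": spec.qr_payload_id, "edge_mm": spec.qr_edge_mm},
        sort_keys=True,
    )
    mat = qr.encode(payload)
    D = mat.shape[0]
    side = spec.qr_edge_mm * spec.pixels_per_mm
    scale = side / D
    quiet = int(np.ceil(4 * scale))
    n = int(np.ceil(side))
    x0 = int(round((spec.width - n) / 2.0))
    y0 = max(quiet, int(round(0.06 * spec.height)))
    if y0 + n + quiet >= img.shape[0] or x0 < quiet or x0 + n + quiet >= img.shape[1]:
        raise ValidationError(
            "qr_edge_mm: fiducial does not fit in the frame at this scale"
        )
    img[y0 - quiet:y0 + n + quiet, x0 - quiet:x0 + n + quiet] = 245.0
    ii, jj = np.mgrid[0:n, 0:n]
    mi = np.clip((ii / scale).astype(int), 0, D - 1)
    mj = np.clip((jj / scale).astype(int), 0, D - 1)
    block = np.where(mat[mi, mj], 16.0, 245.0)
    img[y0:y0 + n, x0:x0 + n] = block[..., None]


def _to_original(points, spec: EyeSceneSpec) -> np.ndarray:
    """Map canonical-frame points into the tilted original frame."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    piv = spec.pivot
    m = rotation_matrix(spec.head_tilt_deg)
    return (pts - piv) @ m.T + piv


def _lid_contour(eye: EyeSpec, upper: bool, n: int = 7) -> np.ndarray:
    cx, cy = eye.center
    R = eye.limbus_radius
    a, b = OPEN_A_FRAC * R, OPEN_B_FRAC * R
    occ = eye.lid_occlusion_deg[0 if upper else 1]
    xs = cx + a * np.linspace(-0.9, 0.9, n)
    u = (xs - cx) / a
    aperture = np.minimum(b * np.sqrt(1.0 - u ** 2), R * np.cos(np.deg2rad(occ)))
    ys = cy - aperture if upper else cy + aperture
    return np.column_stack([xs, ys])


def make_landmark_record(spec: EyeSceneSpec) -> dict:
    """Ground-truth facial-landmark record (original-frame coordinates)."""
    eyes = {}
    for name, eye in (("left", spec.left), ("right", spec.right)):
        cx, cy = eye.center
        a = OPEN_A_FRAC * eye.limbus_radius
        # anatomical left eye sits on the image right: its inner (nasal)
        # corner is the smaller-x corner
        corner_lo = _to_original((cx - a, cy), spec)[0]
        corner_hi = _to_original((cx + a, cy), spec)[0]
        inner, outer = (corner_lo, corner_hi) if name == "left" else (corner_hi, corner_lo)
        eyes[name] = {
            "inner_corner": inner.tolist(),
            "outer_corner": outer.tolist(),
            "upper_lid": _to_original(_lid_contour(eye, True), spec).tolist(),
            "lower_lid": _to_original(_lid_contour(eye, False), spec).tolist(),
        }
    return {
        "image_size": [spec.width, spec.height],
        "head_tilt_deg": spec.head_tilt_deg,
        "eyes": eyes,
        "source": "synthetic-truth",
    }


def scene_truth(spec: EyeSceneSpec,
                config: screen.ScreeningConfig | None = None) -> SceneTruth:
    """Exact measurements and condition labels for a scene spec."""
    config = config or screen.ScreeningConfig(flash_side=spec.flash_side)
    alpha = 1.0 / spec.pixels_per_mm
    offsets = screen.EyeOffsets(
        dx_left=spec.left.clr_offset[0], dy_left=spec.left.clr_offset[1],
        dx_right=spec.right.clr_offset[0], dy_right=spec.right.clr_offset[1],
    )
    gaze = screen.binocular_deviation(offsets, alpha, config.d_mm)

    @dataclass
    class _TruthCrescent:
        width_mm: float
        side: str
        full_pupil: bool = False

    def side_of(eye: EyeSpec) -> str:
        return eye.crescent_side if eye.crescent_width_mm > 0 else screen.NO_CRESCENT

    cl = _TruthCrescent(spec.left.crescent_width_mm, side_of(spec.left))
    cr = _TruthCrescent(spec.right.crescent_width_mm, side_of(spec.right))
    flags = screen.classify(gaze, cl, cr, config)
    labels = {
        "strabismus": flags.strabismus,
        "myopia_left": bool(flags.refractive_left
                            and flags.direction_left == screen.MYOPIC),
        "myopia_right": bool(flags.refractive_right
                             and flags.direction_right == screen.MYOPIC),
        "anisometropia": flags.anisometropia,
    }
    ipd = screen.interpupillary_distance(
        spec.left.center, spec.right.center, alpha
    )
    return SceneTruth(
        alpha_mm_per_px=alpha,
        offsets=offsets,
        gaze=gaze,
        crescent_width_left_mm=spec.left.crescent_width_mm,
        crescent_width_right_mm=spec.right.crescent_width_mm,
        crescent_side_left=side_of(spec.left),
        crescent_side_right=side_of(spec.right),
        limbus_center_left=tuple(map(float, spec.left.center)),
        limbus_center_right=tuple(map(float, spec.right.center)),
        limbus_radius_left=spec.left.limbus_radius,
        limbus_radius_right=spec.right.limbus_radius,
        ipd_mm=ipd,
        head_tilt_deg=spec.head_tilt_deg,
        landmarks=make_landmark_record(spec),
        labels=labels,
    )


def render_exam(spec: EyeSceneSpec):
    """Render the (Hirschberg still, red-reflex frame, SceneTruth) triple."""
    spec.validate()
    xc, yc = _canonical_grid(spec)
    rng = np.random.default_rng(spec.seed)
    images = []
    for kind in ("hirschberg", "redreflex"):
        img = np.empty((spec.height, spec.width, 3), dtype=np.float64)
        img[:] = np.asarray(spec.skin_rgb, dtype=np.float64)
        for eye in (spec.left, spec.right):
            pupil_r = (
                max(2.0, HIRSCHBERG_PUPIL_FRAC * eye.pupil_radius)
                if kind == "hirschberg" else eye.pupil_radius
            )
            _render_eye(img, xc, yc, eye, spec, pupil_r,
                        crescent=(kind == "redreflex"))
        if spec.embed_qr:
            _embed_qr(img, spec)
        if spec.noise_sigma > 0:
            img += rng.normal(0.0, spec.noise_sigma, img.shape)
        images.append(np.clip(np.rint(img), 0, 255).astype(np.uint8))
    return images[0], images[1], scene_truth(spec)


def render_scale_fiducial(payload_id: str, edge_mm: float,
                          pixels_per_mm: float):
    """Standalone QR fiducial region: (RGB image, true alpha mm/px).

    The symbol is drawn at ``edge_mm * pixels_per_mm`` pixels on a side
    with a 4-module quiet zone; true alpha is ``1 / pixels_per_mm``.
    """
    if not edge_mm > 0:
        raise ValidationError("edge_mm must be > 0")
    if not pixels_per_mm > 0:
        raise ValidationError("pixels_per_mm must be > 0")
    payload = json.dumps({"id": payload_id, "edge_mm": edge_mm}, sort_keys=True)
    mat = qr.encode(payload)
    D = mat.shape[0]
    side = edge_mm * pixels_per_mm
    scale = side / D
    quiet = int(np.ceil(4 * scale))
    n = int(np.ceil(side))
    img = np.full((n + 2 * quiet, n + 2 * quiet, 3), 245.0)
    ii, jj = np.mgrid[0:n, 0:n]
    mi = np.clip((ii / scale).astype(int), 0, D - 1)
    mj = np.clip((jj / scale).astype(int), 0, D - 1)
    img[quiet:quiet + n, quiet:quiet + n] = np.where(
        mat[mi, mj], 16.0, 245.0
    )[..., None]
    return img.astype(np.uint8), 1.0 / pixels_per_mm


# ----------------------------------------------------------------------------
# Cohorts
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Population model for a synthetic screening cohort.

    Prevalences mirror the emulated field cohort: one fifth of examinees
    with suspected strabismus; myopia is a per-eye probability.  Affected
    deviation angles and crescent widths sit well above the screening
    cutoffs, unaffected ones well below, as in a screening population where
    the conditions of interest are frank rather than borderline.
    ``blink_fraction`` of examinees blink on the first attempt (the
    observed cause of retakes), yielding a closed-eye first image pair plus
    an open retry.
    """

    n: int = 100
    prev_strabismus: float = 0.20
    prev_myopia: float = 0.30  # per eye
    prev_anisometropia: float = 0.10
    strab_angle_deg: tuple[float, float] = (13.0, 18.0)  # affected |theta|
    normal_angle_deg: tuple[float, float] = (0.0, 3.0)
    myopic_width_mm: tuple[float, float] = (1.4, 2.6)
    normal_width_mm: tuple[float, float] = (0.0, 0.5)
    noise_sigma: float = 0.0
    blink_fraction: float = 0.13
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        for name in ("prev_strabismus", "prev_myopia", "prev_anisometropia",
                     "blink_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")


def _sample_widths(rng, myopia_ex: bool, aniso: bool, cohort: CohortSpec):
    """Crescent widths for the sampled examinee-level condition flags.

    Widths are kept clear of the 1 mm screening cutoffs (affected well
    above, unaffected well below, inter-eye differences either frank or
    small) so that truth labels are stable under sub-0.1 mm measurement
    error.  Anisometropia without binocular myopia is realized as a
    unilateral crescent, which is also what makes the inter-eye difference
    large; its wider eye is necessarily myopic.
    """
    lo_m, hi_m = cohort.myopic_width_mm
    lo_n, hi_n = cohort.normal_width_mm

    def normal_width():
        # refractive error below the reflex threshold produces no
        # crescent at all; otherwise a mild but optically formed one
        if rng.random() < 0.4:
            return 0.0
        return rng.uniform(max(lo_n, 0.25), hi_n)

    if not myopia_ex and not aniso:
        wl, wr = normal_width(), normal_width()
    elif myopia_ex and not aniso:
        wl = rng.uniform(lo_m, min(hi_m, lo_m + 0.6))
        wr = float(np.clip(wl + rng.uniform(-0.6, 0.6), lo_m, hi_m))
    elif myopia_ex and aniso:
        narrow = rng.uniform(lo_m, lo_m + 0.3)
        wide = narrow + rng.uniform(1.3, 1.6)
        wl, wr = (wide, narrow) if rng.random() < 0.5 else (narrow, wide)
    else:  # unilateral myopia realizing the anisometropia
        narrow = 0.0  # the fellow eye has no significant error: no reflex
        wide = rng.uniform(lo_m + 0.1, lo_m + 0.7)
        wl, wr = (wide, narrow) if rng.random() < 0.5 else (narrow, wide)
    return wl, wr


def sample_scene_specs(cohort: CohortSpec, index: int,
                       rng: np.random.Generator) -> tuple[EyeSceneSpec, bool]:
    """Scene spec for one examinee; returns (spec, blinks_first_attempt)."""
    ppmm = rng.uniform(9.2, 10.2)
    alpha = 1.0 / ppmm
    ipd_mm = rng.uniform(54.0, 60.0)
    limbus_mm = rng.uniform(5.2, 5.9)
    R = limbus_mm * ppmm
    pupil = rng.uniform(0.55, 0.68) * R
    width, height = 1024, 704
    cx_mid = width / 2.0 + rng.uniform(-6, 6)
    cy = 530.0 + rng.uniform(-8, 8)
    half = ipd_mm * ppmm / 2.0
    tilt = rng.uniform(-8.0, 8.0)
    occ = rng.uniform(0.0, 25.0)

    d_mm = 20.0
    strab = rng.random() < cohort.prev_strabismus
    myopia_ex = rng.random() < cohort.prev_myopia
    aniso = rng.random() < cohort.prev_anisometropia

    # shared fixation offset (cancels in the binocular difference)
    base_dx = rng.uniform(-3.0, 3.0)
    base_dy = rng.uniform(-3.0, 3.0)

    def angle_to_px(theta_deg):
        return d_mm * np.tan(np.deg2rad(theta_deg)) / (2.0 * alpha)

    if strab:
        theta = rng.uniform(*cohort.strab_angle_deg) * rng.choice([-1.0, 1.0])
        axis = rng.choice(["horizontal", "vertical"], p=[0.7, 0.3])
        eye_dev = rng.choice(["left", "right"])
    else:
        theta = rng.uniform(*cohort.normal_angle_deg) * rng.choice([-1.0, 1.0])
        axis = "horizontal"
        eye_dev = rng.choice(["left", "right"])
    dev_px = angle_to_px(theta)
    offs = {"left": [base_dx, base_dy], "right": [base_dx, base_dy]}
    offs[eye_dev][0 if axis == "horizontal" else 1] += dev_px

    wl, wr = _sample_widths(rng, myopia_ex, aniso, cohort)

    def eye(name, cx, w):
        return EyeSpec(
            center=(cx, cy),
            limbus_radius=R,
            pupil_radius=pupil,
            clr_offset=tuple(offs[name]),
            crescent_width_mm=float(w),
            crescent_side=screen.TOWARD_FLASH,
            lid_occlusion_deg=(occ, occ * rng.uniform(0.3, 1.0)),
        )

    skin = tuple(int(v) for v in (
        214 + rng.integers(-15, 15), 160 + rng.integers(-12, 12),
        120 + rng.integers(-10, 10)))
    # near-neutral dark iris: the emulated population has black-brown
    # limbi in high contrast to the sclera, and a low chroma keeps the
    # HSV saturation (chroma over value) of dark pixels away from skin
    iris_v = int(rng.integers(24, 37))
    iris = (iris_v, max(0, iris_v - 2), max(0, iris_v - 3))
    spec = EyeSceneSpec(
        width=width, height=height,
        left=eye("left", cx_mid + half, wl),
        right=eye("right", cx_mid - half, wr),
        skin_rgb=skin,
        iris_rgb=iris,
        head_tilt_deg=float(tilt),
        pixels_per_mm=float(ppmm),
        noise_sigma=cohort.noise_sigma,
        seed=int(rng.integers(0, 2 ** 31 - 1)),
        qr_payload_id=f"S{index:04d}",
    )
    blink = rng.random() < cohort.blink_fraction
    return spec, blink


def generate_cohort(cohort: CohortSpec, out_dir) -> "Path":
    """Render a whole cohort to ``out_dir``; returns the manifest path.

    Writes per-case PNG image pairs, landmark JSON, truth JSON, and a
    manifest CSV with columns id, hirschberg_path, redreflex_path,
    landmarks_path, truth_path (semicolon-separated per-attempt lists in
    the path columns when a blink retake is present).  Byte-identical under
    a fixed seed.
    """
    from PIL import Image

    cohort.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cohort.seed)
    rows = []
    for i in range(cohort.n):
        spec, blink = sample_scene_specs(cohort, i, rng)
        case_id = spec.qr_payload_id
        attempts = []
        if blink:
            closed = dataclasses.replace(
                spec,
                left=dataclasses.replace(spec.left, lid_occlusion_deg=(80.0, 80.0)),
                right=dataclasses.replace(spec.right, lid_occlusion_deg=(80.0, 80.0)),
            )
            attempts.append((closed, "a0"))
            attempts.append((dataclasses.replace(spec, seed=spec.seed + 1), "a1"))
        else:
            attempts.append((spec, "a0"))
        h_paths, r_paths, l_paths = [], [], []
        truth = None
        for att_spec, tag in attempts:
            hirsch, red, att_truth = render_exam(att_spec)
            hp = out / f"{case_id}_{tag}_hirschberg.png"
            rp = out / f"{case_id}_{tag}_redreflex.png"
            lp = out / f"{case_id}_{tag}_landmarks.json"
            Image.fromarray(hirsch).save(hp)
            Image.fromarray(red).save(rp)
            lp.write_text(json.dumps(att_truth.landmarks, sort_keys=True, indent=1))
            h_paths.append(hp.name)
            r_paths.append(rp.name)
            l_paths.append(lp.name)
            truth = att_truth  # the open-eye geometry is the case truth
        tp = out / f"{case_id}_truth.json"
        tp.write_text(truth.to_json(indent=1))
        rows.append({
            "id": case_id,
            "hirschberg_path": ";".join(h_paths),
            "redreflex_path": ";".join(r_paths),
            "landmarks_path": ";".join(l_paths),
            "truth_path": tp.name,
        })
    import pandas as pd

    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
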