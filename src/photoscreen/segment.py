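"""Bespoke image operators of the photoscreening pipeline.

All operators work on 8-bit RGB eye patches in patch coordinates
(0-based, x right / y down, pixel centers at integer coordinates):

* skin-masked region-of-interest extraction (hue/saturation match against
  the surrounding skin),
* IsoData automatic thresholding of the ROI histogram (sclera/iris split),
* an arc-restricted circle Hough transform for the limbus in the Hirschberg
  still: edge points vote only for centers they sit within +/-45 degrees of
  horizontally, so eyelid-covered top/bottom arcs contribute nothing,
* fixed-radius contrast-maximizing limbus refinement for the red-reflex
  frame,
* CLR spot extraction (maximal-intensity cluster + inscribed circle),
* red-reflex crescent extraction (color/brightness filter + circumscribed
  minimum-area ellipse + horizontal width in mm),
* QR scale decoding (frontal-plane mm-per-pixel calibration).

"Brightness" is (R+G+B)/3 throughout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import qr
from .errors import DetectionError, ScaleDecodeError, ValidationError

# ----------------------------------------------------------------------------
# Result types
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class LimbusCircle:
    """Detected limbus: center/radius in patch coordinates plus a score
    (Hough votes for the Hirschberg pass, annulus contrast for the
    photorefraction pass)."""

    center: tuple[float, float]
    radius: float
    score: float
    source: str  # "hirschberg" | "photorefraction"

    def to_dict(self) -> dict:
        return {
            "center": list(self.center),
            "radius": self.radius,
            "score": self.score,
            "source": self.source,
        }


@dataclass(frozen=True)
class CLRSpot:
    """Corneal-luminous-reflection spot: inscribed-circle center/radius."""

    center: tuple[float, float]
    radius: float
    pixel_count: int

    def to_dict(self) -> dict:
        return {
            "center": list(self.center),
            "radius": self.radius,
            "pixel_count": self.pixel_count,
        }


@dataclass(frozen=True)
class Crescent:
    """Red-reflex crescent measurement.

    ``pixels`` is an (N, 2) array of (x, y) patch coordinates; ``ellipse``
    is the minimum-area circumscribing ellipse (center, semi-axes,
    orientation deg) or None for an empty set; ``width_mm`` is the
    horizontal (flash-axis) extent of the pixel set times the frontal-plane
    scale.  When the retained area covers most of the limbus disk the pupil
    is fully lit and the width is reported as the limbus diameter.
    """

    pixels: np.ndarray
    ellipse: tuple[tuple[float, float], tuple[float, float], float] | None
    width_mm: float
    side: str  # toward-flash | away-from-flash | none
    full_pupil: bool
    pixel_count: int

    def to_dict(self) -> dict:
        return {
            "ellipse": None if self.ellipse is None else {
                "center": list(self.ellipse[0]),
                "semi_axes": list(self.ellipse[1]),
                "orientation_deg": self.ellipse[2],
            },
            "width_mm": self.width_mm,
            "side": self.side,
            "full_pupil": self.full_pupil,
            "pixel_count": self.pixel_count,
        }


@dataclass(frozen=True)
class ScaleCalibration:
    """Frontal-plane scale decoded from the QR fiducial."""

    alpha_mm_per_px: float
    examinee_id: str
    edge_mm: float
    corners: np.ndarray  # (4, 2) symbol corner points, px

    def __post_init__(self):
        if not self.alpha_mm_per_px > 0:
            raise ValidationError("alpha_mm_per_px must be > 0")

    def to_dict(self) -> dict:
        return {
            "alpha_mm_per_px": self.alpha_mm_per_px,
            "examinee_id": self.examinee_id,
            "edge_mm": self.edge_mm,
            "corners": np.asarray(self.corners).tolist(),
        }


@dataclass(frozen=True)
class SkinStats:
    """Skin appearance model: circular-mean hue (deg) and mean saturation."""

    hue_deg: float
    saturation: float
    hue_tol_deg: float = 10.0
    sat_tol: float = 0.12

    def __post_init__(self):
        if not 0.0 <= self.saturation <= 1.0:
            raise ValidationError("saturation must be in [0, 1]")


# ----------------------------------------------------------------------------
# IsoData thresholding
# ----------------------------------------------------------------------------


def isodata_threshold(histogram) -> int:
    """IsoData (intermeans) threshold of a 256-bin intensity histogram.

    Iterates t <- floor(((mean of levels <= t) + (mean of levels > t)) / 2)
    starting from the midpoint of the occupied range, until the fixed
    point.  The floor makes the update map monotone on the integer levels,
    so the iteration always terminates at a true fixed point (half-up
    rounding can oscillate between adjacent bins).  Requires at least two
    distinct occupied bins (otherwise no sclera/iris boundary exists).
    """
    hist = np.asarray(histogram, dtype=np.int64)
    if hist.shape != (256,):
        raise ValidationError("histogram must have 256 bins")
    if np.any(hist < 0):
        raise ValidationError("histogram counts must be >= 0")
    occupied = np.flatnonzero(hist)
    if occupied.size < 2:
        raise DetectionError(
            "histogram has fewer than 2 occupied bins; no boundary exists",
            stage="isodata_threshold",
        )
    levels = np.arange(256, dtype=np.float64)
    t = int((occupied[0] + occupied[-1]) // 2)
    seen = set()
    while t not in seen:
        seen.add(t)
        lo_w = hist[: t + 1].sum()
        hi_w = hist[t + 1:].sum()
        if lo_w == 0:
            t += 1
            continue
        if hi_w == 0:
            t -= 1
            continue
        mean_lo = float(levels[: t + 1] @ hist[: t + 1]) / lo_w
        mean_hi = float(levels[t + 1:] @ hist[t + 1:]) / hi_w
        t = int(np.floor((mean_lo + mean_hi) / 2.0))
    return t


# ----------------------------------------------------------------------------
# Skin-masked ROI
# ----------------------------------------------------------------------------


def _hue_sat(rgb: np.ndarray):
    """Hue (deg) and saturation of an RGB uint8 array (HSV model)."""
    from skimage.color import rgb2hsv

    hsv = rgb2hsv(rgb)
    return hsv[..., 0] * 360.0, hsv[..., 1]


def estimate_skin_stats(patch: np.ndarray, border_frac: float = 0.10,
                        hue_tol_deg: float = 10.0,
                        sat_tol: float = 0.12) -> SkinStats:
    """Estimate skin hue/saturation from the outer border frame of a patch."""
    h, w = patch.shape[:2]
    bh = max(1, int(round(border_frac * h)))
    bw = max(1, int(round(border_frac * w)))
    frame = np.ones((h, w), dtype=bool)
    frame[bh:h - bh, bw:w - bw] = False
    hue, sat = _hue_sat(patch)
    # medians, and a circular location estimate for hue, keep the model on
    # the skin even when another structure intrudes into the border frame
    hb = np.deg2rad(hue[frame])
    center = np.arctan2(np.median(np.sin(hb)), np.median(np.cos(hb)))
    dh = (hb - center + np.pi) % (2 * np.pi) - np.pi
    med_hue = np.degrees(center + np.median(dh)) % 360.0
    return SkinStats(
        hue_deg=float(med_hue),
        saturation=float(np.median(sat[frame])),
        hue_tol_deg=hue_tol_deg,
        sat_tol=sat_tol,
    )


def build_roi_mask(patch: np.ndarray, stats: SkinStats | None = None) -> np.ndarray:
    """Binary sclera-limbus-iris region of interest for an eye patch.

    Pixels whose hue and saturation both fall within tolerance of the skin
    statistics are treated as skin; the ROI is the connected non-skin
    component containing the patch center.  ``stats=None`` estimates the
    skin model from the outer 10% border frame of the patch.  Idempotent in
    the sense that masking an already-masked ROI changes nothing.
    """
    patch = np.asarray(patch)
    if patch.size == 0:
        raise ValidationError("patch is empty")
    if stats is None:
        stats = estimate_skin_stats(patch)
    hue, sat = _hue_sat(patch)
    dh = np.abs((hue - stats.hue_deg + 180.0) % 360.0 - 180.0)
    skin = (dh <= stats.hue_tol_deg) & (np.abs(sat - stats.saturation) <= stats.sat_tol)
    # 3x3 majority vote despeckles per-pixel noise flips
    if min(patch.shape[:2]) >= 3:
        skin = ndimage.median_filter(skin.astype(np.uint8), size=3).astype(bool)
    non_skin = ~skin
    labels, _ = ndimage.label(non_skin)
    cy, cx = patch.shape[0] // 2, patch.shape[1] // 2
    window = labels[max(0, cy - 2):cy + 3, max(0, cx - 2):cx + 3]
    seeds = window[window > 0]
    if seeds.size == 0:
        raise DetectionError(
            "ROI is empty: patch center is skin-like", stage="build_roi_mask"
        )
    lab = int(np.bincount(seeds).argmax())
    return labels == lab


# ----------------------------------------------------------------------------
# Arc-restricted circle Hough (Hirschberg image)
# ----------------------------------------------------------------------------


def _brightness(patch: np.ndarray) -> np.ndarray:
    return np.asarray(patch, dtype=np.float64).mean(axis=2)


def _edge_points(gray: np.ndarray, mask: np.ndarray, threshold: float):
    """Boundary pixels of the sub-threshold (dark) region inside the mask."""
    dark = (gray <= threshold) & mask
    interior = ndimage.binary_erosion(dark)
    boundary = dark & ~interior
    ys, xs = np.nonzero(boundary)
    return xs, ys


def _arc_offsets(radius: float, arc_half_deg: float = 45.0):
    """Unit-circle offsets on the left/right arcs, ~1 px angular steps."""
    n = max(8, int(round(np.deg2rad(2 * arc_half_deg) * radius)))
    a = np.deg2rad(np.linspace(-arc_half_deg, arc_half_deg, n))
    angles = np.concatenate([a, a + np.pi])
    return np.cos(angles), np.sin(angles)


def detect_limbus_hirschberg(patch: np.ndarray, mask: np.ndarray,
                             corner_distance: float,
                             radius_bounds: tuple[float, float] = (0.15, 0.45),
                             min_support: int = 20,
                             max_edge_points: int = 400) -> LimbusCircle:
    """Arc-restricted circle Hough detection of the limbus.

    Edge points are the boundary pixels of the dark (sub-IsoData) region of
    the ROI.  Each point votes only for candidate centers from which it is
    seen within +/-45 degrees of horizontal — the left and right limbus
    arcs — so lid-covered top/bottom arcs are never required.  The radius
    range is ``radius_bounds`` times the eye-corner distance in 1 px steps.
    Ties break toward more votes, then larger radius, then smaller y, then
    smaller x; the returned center/radius are refined to sub-pixel precision
    from the vote mass around the peak.
    """
    if not np.any(mask):
        raise DetectionError("empty ROI mask", stage="detect_limbus")
    gray = _brightness(patch)
    hist = np.bincount(
        np.clip(gray[mask].round().astype(int), 0, 255), minlength=256
    )
    thr = isodata_threshold(hist)
    xs, ys = _edge_points(gray, mask, thr)
    if xs.size == 0:
        raise DetectionError("no edge points below threshold",
                             stage="detect_limbus")
    if xs.size > max_edge_points:
        step = int(np.ceil(xs.size / max_edge_points))
        xs, ys = xs[::step], ys[::step]

    h, w = gray.shape
    r_lo = max(3, int(np.floor(radius_bounds[0] * corner_distance)))
    r_hi = max(r_lo + 1, int(np.ceil(radius_bounds[1] * corner_distance)))
    radii = np.arange(r_lo, r_hi + 1)

    best = None  # (votes, radius, -y, -x) lexicographic max
    planes = {}
    for r in radii:
        ox, oy = _arc_offsets(r)
        cx = np.rint(xs[:, None] - r * ox[None, :]).astype(np.int64)
        cy = np.rint(ys[:, None] - r * oy[None, :]).astype(np.int64)
        ok = (cx >= 0) & (cx < w) & (cy >= 0) & (cy < h)
        flat = cy[ok] * w + cx[ok]
        acc = np.bincount(flat, minlength=h * w).reshape(h, w)
        # 3x3 vote mass absorbs +/-1 px discretization spread
        score = ndimage.uniform_filter(acc.astype(np.float64), 3) * 9.0
        idx = np.argmax(score)
        peak_y, peak_x = divmod(int(idx), w)
        peak = score[peak_y, peak_x]
        # ties: argmax resolves within a plane toward smallest y then x;
        # across planes, lexicographic (votes, radius) prefers larger radius
        if best is None or (peak, r) > (best[0], best[1]):
            best = (peak, int(r), peak_x, peak_y)
            planes = {"acc": acc, "score": score}
    votes, r_best, px, py = best
    if votes < min_support:
        raise DetectionError(
            f"limbus support {votes:.0f} below minimum {min_support}",
            stage="detect_limbus",
        )

    # sub-pixel center: vote-mass centroid in a 5x5 window at the best radius
    acc = planes["acc"].astype(np.float64)
    y0, y1 = max(0, py - 2), min(h, py + 3)
    x0, x1 = max(0, px - 2), min(w, px + 3)
    win = acc[y0:y1, x0:x1]
    if win.sum() > 0:
        yy, xx = np.mgrid[y0:y1, x0:x1]
        cx_ref = float((win * xx).sum() / win.sum())
        cy_ref = float((win * yy).sum() / win.sum())
    else:
        cx_ref, cy_ref = float(px), float(py)

    # sub-pixel radius: parabolic fit of the 3x3 vote mass over r-1, r, r+1
    def mass_at(r):
        ox, oy = _arc_offsets(r)
        gx = np.rint(xs[:, None] - r * ox[None, :]).astype(np.int64)
        gy = np.rint(ys[:, None] - r * oy[None, :]).astype(np.int64)
        ok = (np.abs(gx - px) <= 1) & (np.abs(gy - py) <= 1)
        return float(ok.sum())

    r_ref = float(r_best)
    if r_lo < r_best < r_hi:
        m_lo, m_mid, m_hi = mass_at(r_best - 1), mass_at(r_best), mass_at(r_best + 1)
        denom = m_lo - 2 * m_mid + m_hi
        if denom < 0:
            r_ref += float(np.clip(0.5 * (m_lo - m_hi) / denom, -0.5, 0.5))
    # edge points are centers of the outermost dark pixels, which lie about
    # half a pixel inside the true iris rim
    r_ref += 0.5

    return LimbusCircle(
        center=(cx_ref, cy_ref), radius=r_ref, score=float(votes),
        source="hirschberg",
    )


# ----------------------------------------------------------------------------
# Contrast-maximizing refinement (red-reflex image)
# ----------------------------------------------------------------------------


def _annulus_contrast(gray: np.ndarray, centers: np.ndarray, radius: float,
                      arc_half_deg: float = 45.0) -> np.ndarray:
    """Outer-minus-inner annulus contrast at each candidate center.

    Outer annulus r..1.15r, inner 0.85r..r, both restricted to the left and
    right +/-45 degree arcs; sampled bilinearly.
    """
    a = np.deg2rad(np.linspace(-arc_half_deg, arc_half_deg, 48))
    angles = np.concatenate([a, a + np.pi])
    r_in = radius * np.linspace(0.85, 0.98, 4)
    r_out = radius * np.linspace(1.02, 1.15, 4)

    def ring_mean(rads):
        rr = rads[:, None]
        dx = (rr * np.cos(angles)[None, :]).ravel()
        dy = (rr * np.sin(angles)[None, :]).ravel()
        xs = centers[:, 0][:, None] + dx[None, :]
        ys = centers[:, 1][:, None] + dy[None, :]
        coords = np.stack([ys.ravel(), xs.ravel()])
        vals = ndimage.map_coordinates(gray, coords, order=1, mode="nearest")
        return vals.reshape(centers.shape[0], -1).mean(axis=1)

    return ring_mean(r_out) - ring_mean(r_in)


def refine_limbus_photorefraction(patch: np.ndarray, prior: LimbusCircle,
                                  search_px: int = 6,
                                  radius_tol: float = 0.10) -> LimbusCircle:
    """Relocate the limbus in the red-reflex frame at the Hirschberg radius.

    The radius is held to the prior within a +/-``radius_tol`` band; the
    center is chosen on an integer grid within ``search_px`` of the prior to
    maximize arc-restricted annulus contrast, then refined to sub-pixel by a
    separable parabolic fit of the contrast surface.
    """
    gray = _brightness(patch)
    cx0, cy0 = prior.center
    gx = np.arange(int(round(cx0)) - search_px, int(round(cx0)) + search_px + 1)
    gy = np.arange(int(round(cy0)) - search_px, int(round(cy0)) + search_px + 1)
    centers = np.array([(x, y) for y in gy for x in gx], dtype=float)

    r_lo = max(3, int(np.floor(prior.radius * (1 - radius_tol))))
    r_hi = int(np.ceil(prior.radius * (1 + radius_tol)))
    best = None
    for r in range(r_lo, r_hi + 1):
        contrast = _annulus_contrast(gray, centers, float(r))
        i = int(np.argmax(contrast))
        if best is None or contrast[i] > best[0]:
            best = (float(contrast[i]), float(r), i, contrast.copy())
    score, r_best, i_best, surface = best
    if score <= 0:
        raise DetectionError("no positive limbus contrast in red-reflex frame",
                             stage="refine_limbus")
    surf = surface.reshape(len(gy), len(gx))
    iy, ix = divmod(i_best, len(gx))

    def para(f_m, f_0, f_p):
        denom = f_m - 2 * f_0 + f_p
        return float(np.clip(0.5 * (f_m - f_p) / denom, -0.5, 0.5)) if denom < 0 else 0.0

    dx = para(surf[iy, ix - 1], surf[iy, ix], surf[iy, ix + 1]) if 0 < ix < len(gx) - 1 else 0.0
    dy = para(surf[iy - 1, ix], surf[iy, ix], surf[iy + 1, ix]) if 0 < iy < len(gy) - 1 else 0.0
    return LimbusCircle(
        center=(float(gx[ix]) + dx, float(gy[iy]) + dy),
        radius=r_best, score=score, source="photorefraction",
    )


# ----------------------------------------------------------------------------
# CLR spot
# ----------------------------------------------------------------------------

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def detect_clr(patch: np.ndarray, limbus: LimbusCircle,
               intensity_tol_frac: float = 0.02) -> CLRSpot:
    """Corneal-luminous-reflection spot inside the limbus disk.

    Candidate pixels are those whose minimum channel value reaches the disk
    maximum of that statistic within a tolerance (default 2% of the dynamic
    range).  The largest 4-connected component is kept (ties broken by the
    topmost-then-leftmost centroid) and an inscribed circle fitted at the
    component's distance-transform maximum.
    """
    arr = np.asarray(patch, dtype=np.float64)
    h, w = arr.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = limbus.center
    disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= limbus.radius ** 2
    if not np.any(disk):
        raise DetectionError("limbus disk lies outside the patch",
                             stage="detect_clr")
    minchan = arr.min(axis=2)
    vmax = minchan[disk].max()
    cand = disk & (minchan >= vmax - intensity_tol_frac * 255.0)
    if not np.any(cand):
        raise DetectionError("no flash reflection found", stage="detect_clr")
    labels, n = ndimage.label(cand, structure=_FOUR_CONN)
    sizes = ndimage.sum_labels(cand, labels, index=np.arange(1, n + 1))
    biggest = sizes.max()
    tied = np.flatnonzero(np.isclose(sizes, biggest)) + 1
    if len(tied) > 1:
        cents = ndimage.center_of_mass(cand, labels, index=tied)  # (y, x)
        order = sorted(range(len(tied)), key=lambda i: (cents[i][0], cents[i][1]))
        lab = int(tied[order[0]])
    else:
        lab = int(tied[0])
    comp = labels == lab

    dist = ndimage.distance_transform_edt(comp)
    dmax = dist.max()
    # centroid of the near-maximal plateau gives a sub-pixel, symmetric center
    plateau = dist >= dmax - 1.0
    pys, pxs = np.nonzero(plateau)
    weights = dist[plateau]
    center = (float((pxs * weights).sum() / weights.sum()),
              float((pys * weights).sum() / weights.sum()))
    return CLRSpot(center=center, radius=float(dmax),
                   pixel_count=int(comp.sum()))


def inscribed_circle(component: np.ndarray):
    """Largest circle fully inside a boolean component (center, radius).

    Integer-precision variant used by the oracle comparisons: the center is
    the distance-transform argmax (row-major first on ties).
    """
    dist = ndimage.distance_transform_edt(component)
    idx = int(np.argmax(dist))
    y, x = divmod(idx, component.shape[1])
    return (float(x), float(y)), float(dist[y, x])


# ----------------------------------------------------------------------------
# Minimum-area enclosing ellipse (Khachiyan) and crescent extraction
# ----------------------------------------------------------------------------


def min_enclosing_ellipse(points, tol: float = 1e-6, max_iter: int = 5000):
    """Minimum-area ellipse enclosing 2-D ``points``.

    Khachiyan's barycentric-coordinate ascent on the dual (D-optimal design)
    problem.  Returns (center (x, y), semi-axes (a, b) with a >= b,
    orientation deg of the a-axis, counterclockwise-on-screen from +x).
    Degenerate (collinear) inputs get a hair of regularization so the result
    is a valid, thin ellipse.
    """
    P = np.asarray(points, dtype=np.float64)
    if P.ndim != 2 or P.shape[1] != 2 or len(P) == 0:
        raise ValidationError("points must be a non-empty (N, 2) array")
    if len(P) == 1:
        return (float(P[0, 0]), float(P[0, 1])), (0.5, 0.5), 0.0
    N = len(P)
    Q = np.column_stack([P, np.ones(N)]).T  # 3 x N
    u = np.full(N, 1.0 / N)
    for _ in range(max_iter):
        X = (Q * u) @ Q.T
        try:
            Xinv = np.linalg.inv(X)
        except np.linalg.LinAlgError:
            Xinv = np.linalg.inv(X + 1e-9 * np.eye(3))
        M = np.einsum("ji,jk,ki->i", Q, Xinv, Q)
        j = int(np.argmax(M))
        mx = M[j]
        # KKT gap: at the optimum every support weight satisfies
        # q^T X^-1 q = d+1 = 3; stop when the worst violation is tiny
        if mx - 3.0 <= 3.0 * tol:
            break
        step = (mx - 3.0) / (3.0 * (mx - 1.0))
        u *= 1.0 - step
        u[j] += step
    c = P.T @ u
    S = (P.T * u) @ P - np.outer(c, c)
    S = S + 1e-9 * np.trace(S + 1e-12 * np.eye(2)) * np.eye(2)
    A = np.linalg.inv(S) / 2.0
    # guarantee containment numerically: scale so the farthest point sits on
    # the boundary
    d = np.einsum("ni,ij,nj->n", P - c, A, P - c)
    A /= max(d.max(), 1e-12)
    evals, evecs = np.linalg.eigh(A)
    axes = 1.0 / np.sqrt(evals)  # descending semi-axes after eigh's ascending evals
    a, b = float(axes[0]), float(axes[1])
    v = evecs[:, 0]  # eigenvector of the smallest eigenvalue = major axis
    angle = float(np.degrees(np.arctan2(-v[1], v[0])) % 180.0)
    return (float(c[0]), float(c[1])), (a, b), angle


def detect_crescent(patch: np.ndarray, limbus: LimbusCircle,
                    clr: CLRSpot | None, alpha_mm_per_px: float,
                    flash_side: str = "left",
                    min_component_px: int = 5,
                    full_pupil_frac: float = 0.70,
                    supersample: int = 2) -> Crescent:
    """Red-reflex crescent pixels, enclosing ellipse and width.

    Raw crescent pixels lie inside the limbus disk, outside the CLR spot,
    and satisfy (red > green + blue AND brightness more than twice the
    median brightness of the limbus-disk pixels) OR a saturated red channel.
    Components below ``min_component_px`` pixels are discarded.  The width
    is the horizontal (flash-displacement-axis) pixel extent of the retained
    set times ``alpha_mm_per_px``; the side compares the set's centroid with
    the limbus center given the flash geometry; a retained area of at least
    ``full_pupil_frac`` of the limbus disk flags a fully lit pupil, whose
    width is reported as the limbus diameter.
    """
    if not alpha_mm_per_px > 0:
        raise ValidationError("alpha_mm_per_px must be > 0")
    if flash_side not in ("left", "right"):
        raise ValidationError("flash_side must be 'left' or 'right'")
    if supersample < 1:
        raise ValidationError("supersample must be >= 1")
    arr = np.asarray(patch, dtype=np.float64)
    s = int(supersample)
    if s > 1:
        # bilinear supersampling turns the pixel-quantized horizontal extent
        # into a sub-pixel measurement (the width bound is tighter than the
        # native pixel pitch at typical scales)
        from skimage.transform import rescale

        arr = rescale(arr, s, channel_axis=2, order=1, anti_aliasing=False)

    def up(v):  # patch coordinate -> supersampled grid coordinate
        return v * s + (s - 1) / 2.0

    h, w = arr.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = up(limbus.center[0]), up(limbus.center[1])
    radius = limbus.radius * s
    disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2

    exclude = np.zeros((h, w), dtype=bool)
    if clr is not None:
        # pad the inscribed circle: saturated halo pixels around the spot
        # must not masquerade as crescent
        ex_r = (clr.radius + 3.0) * s
        exclude = ((xx - up(clr.center[0])) ** 2
                   + (yy - up(clr.center[1])) ** 2 <= ex_r ** 2)

    base = disk & ~exclude
    r_ch, g_ch, b_ch = arr[..., 0], arr[..., 1], arr[..., 2]
    bright = arr.mean(axis=2)
    if not np.any(base):
        retained = np.zeros((h, w), dtype=bool)
    else:
        med = float(np.median(bright[base]))
        cand = base & (
            ((r_ch > g_ch + b_ch) & (bright > 2.0 * med)) | (r_ch >= 255)
        )
        # 8-connectivity: a thin crescent arc fragments under 4-connectivity
        labels, n = ndimage.label(cand, structure=np.ones((3, 3), dtype=bool))
        retained = np.zeros((h, w), dtype=bool)
        if n:
            sizes = ndimage.sum_labels(cand, labels, index=np.arange(1, n + 1))
            for lab in np.flatnonzero(sizes >= min_component_px * s * s) + 1:
                retained |= labels == lab

    pys, pxs = np.nonzero(retained)
    if pxs.size == 0:
        return Crescent(pixels=np.empty((0, 2), dtype=float), ellipse=None,
                        width_mm=0.0, side="none", full_pupil=False,
                        pixel_count=0)

    def down(v):  # supersampled grid coordinate -> patch coordinate
        return (v - (s - 1) / 2.0) / s

    pts = np.column_stack([down(pxs.astype(float)), down(pys.astype(float))])
    # Sub-pixel horizontal extent: integrate per-column crescent coverage.
    # The red-dominance score C = R - G - B is linear in the blend
    # fraction of a partially covered pixel, so each boundary column's
    # peak score, normalized between the local background and the
    # crescent plateau, estimates its fractional coverage.
    C = r_ch - g_ch - b_ch
    x0, x1 = int(pxs.min()), int(pxs.max())
    win = slice(max(0, x0 - 2), min(w, x1 + 3))
    sel_win = base[:, win]
    ret_win = retained[:, win]
    neighborhood = sel_win & ~ret_win
    bg = float(np.median(C[:, win][neighborhood])) if neighborhood.any() else -1.0
    plateau = float(np.percentile(C[retained], 90))
    denom = max(plateau - bg, 1e-6)
    Cw = np.where(sel_win, C[:, win], -np.inf)
    col_max = Cw.max(axis=0)
    frac = np.clip((col_max - bg) / denom, 0.0, 1.0)
    frac[~np.isfinite(col_max)] = 0.0
    extent_px = float(frac.sum()) / s
    width_mm = alpha_mm_per_px * extent_px
    area_frac = pxs.size / (np.pi * radius ** 2)
    full = area_frac >= full_pupil_frac
    if full:
        width_mm = alpha_mm_per_px * 2.0 * limbus.radius

    centroid_x = float(pxs.mean())
    on_flash = centroid_x < cx if flash_side == "left" else centroid_x > cx
    side = "toward-flash" if on_flash else "away-from-flash"

    from scipy.spatial import ConvexHull

    try:
        hull = ConvexHull(pts)
        hull_pts = pts[hull.vertices]
    except Exception:  # degenerate (collinear) sets
        hull_pts = pts
    ellipse = min_enclosing_ellipse(hull_pts)
    return Crescent(pixels=pts, ellipse=ellipse, width_mm=float(width_mm),
                    side=side, full_pupil=bool(full),
                    pixel_count=int(round(pxs.size / (s * s))))


# ----------------------------------------------------------------------------
# QR scale decoding
# ----------------------------------------------------------------------------


def decode_scale(image: np.ndarray) -> ScaleCalibration:
    """Decode the QR scale fiducial and compute alpha (mm per pixel).

    The payload must be JSON ``{"id": ..., "edge_mm": ...}``; the symbol
    side in pixels is the mean of the four side lengths of the decoded
    corner quadrilateral.
    """
    text, corners = qr.decode_image(image)
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ScaleDecodeError(f"QR payload is not valid JSON: {exc}") from exc
    if not isinstance(payload, dict) or "edge_mm" not in payload:
        raise ScaleDecodeError("QR payload missing required key 'edge_mm'")
    edge_mm = float(payload["edge_mm"])
    if edge_mm <= 0:
        raise ScaleDecodeError("QR payload edge_mm must be > 0")
    sides = [
        float(np.linalg.norm(corners[i] - corners[(i + 1) % 4])) for i in range(4)
    ]
    side_px = float(np.mean(sides))
    return ScaleCalibration(
        alpha_mm_per_px=edge_mm / side_px,
        examinee_id=str(payload.get("id", "")),
        edge_mm=edge_mm,
        corners=corners,
    )
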