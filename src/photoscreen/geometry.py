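"""Shared 2-D geometry helpers.

Coordinate convention throughout the package: 0-based pixel coordinates,
x right / y down, pixel centers at integer coordinates.  Angles given in
degrees; a positive rotation is counterclockwise as seen on screen (which,
with y pointing down, is a clockwise rotation in right-handed math axes).
"""

from __future__ import annotations

import numpy as np


def rotation_matrix(angle_deg: float) -> np.ndarray:
    """2x2 matrix rotating points counterclockwise-on-screen by ``angle_deg``.

    With y down, on-screen CCW by 90 deg maps (1, 0) -> (0, -1).
    """
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, s], [-s, c]])


def rotate_points(points, angle_deg: float, pivot) -> np.ndarray:
    """Rotate ``points`` (N,2) or (2,) about ``pivot`` by ``angle_deg`` (on-screen CCW)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    pivot = np.asarray(pivot, dtype=float)
    out = (pts - pivot) @ rotation_matrix(angle_deg).T + pivot
    return out[0] if np.asarray(points).ndim == 1 else out


def affine_about(angle_deg: float, pivot) -> np.ndarray:
    """3x3 homogeneous matrix for rotation about ``pivot`` (x, y order)."""
    m = np.eye(3)
    m[:2, :2] = rotation_matrix(angle_deg)
    pivot = np.asarray(pivot, dtype=float)
    m[:2, 2] = pivot - m[:2, :2] @ pivot
    return m
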