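"""Small shared geometry helpers."""
from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize near-zero vector")
    return v / n


def orthonormal_frame(normal: np.ndarray, hint: np.ndarray | None = None):
    """Two unit vectors (u, v) spanning the plane perpendicular to `normal`.

    `u` is the projection of `hint` onto the plane (falls back to the least
    aligned coordinate axis); `v = normal x u`, so (u, v, normal) is
    right-handed.
    """
    n = unit(normal)
    if hint is None:
        hint = np.eye(3)[np.argmin(np.abs(n))]
    h = np.asarray(hint, dtype=float)
    u = h - np.dot(h, n) * n
    if np.linalg.norm(u) < 1e-9:
        h = np.eye(3)[np.argmin(np.abs(n))]
        u = h - np.dot(h, n) * n
    u = unit(u)
    v = np.cross(n, u)
    return u, v


def rot2d(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s], [s, c]])


def moving_average(points: np.ndarray, window: int) -> np.ndarray:
    """Edge-truncated moving average along the first axis of a polyline."""
    if window <= 1 or len(points) <= 2:
        return np.asarray(points, dtype=float).copy()
    pts = np.asarray(points, dtype=float)
    half = window // 2
    out = np.empty_like(pts)
    for i in range(len(pts)):
        lo, hi = max(0, i - half), min(len(pts), i + half + 1)
        out[i] = pts[lo:hi].mean(axis=0)
    return out


def polyline_length(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def arc_length_param(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length, starting at 0."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])
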