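"""Grid overlay rendering and frame-to-frame tracking.

The registered transform maps the Bernard-Hertel grid from the lateral
model projection into the arthroscopic frame, where it is rasterized
semi-transparently (alpha blending on the exact line pixels only, no
anti-aliasing, so every off-line pixel stays bit-identical). A simple
tracker seeds each frame's ICP with the previous transform and falls back
to full SIFT re-initialization when the residual degrades past twice the
running median.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage.draw import line as draw_line

from .bh_grid import BHGrid
from .registration import (RegistrationResult, RigidTransform2D, detect_edges,
                           edge_points, enhance, icp_refine, register_frame)


@dataclass
class OverlaySpec:
    alpha: float = 0.5
    grid_color: tuple[float, float, float] = (0.0, 1.0, 1.0)
    footprint_color: tuple[float, float, float] = (1.0, 0.0, 0.0)
    boundary_color: tuple[float, float, float] = (1.0, 0.0, 0.0)
    line_width: int = 1

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")


def project_grid(
    grid: BHGrid,
    f: RigidTransform2D,
    calib_mm_per_px: float,
    extra_curves_mm: list[np.ndarray] | None = None,
    frame_shape: tuple[int, int] | None = None,
) -> dict:
    """Map grid lines, footprint and boundary curves into frame pixels.

    ``f`` maps model-projection pixel coordinates (grid mm divided by the
    calibration) into frame pixels. Returns polylines in px under keys
    ``cells``, ``d_axis``, ``h_axis``, ``footprint``, ``boundary`` and a
    ``status`` flag ("ok", or "outside" when nothing lands in the frame).
    """
    def to_px(pts_mm):
        return f.apply(np.asarray(pts_mm, dtype=float) / calib_mm_per_px)

    out = {
        "cells": [to_px(c) for c in grid.cells],
        "d_axis": to_px(np.stack([grid.corner(0, 0), grid.corner(1, 0)])),
        "h_axis": to_px(np.stack([grid.corner(0, 0), grid.corner(0, 1)])),
        "footprint": to_px(grid.footprint2d[None])[0],
        "boundary": [to_px(c) for c in (extra_curves_mm or [])],
        "status": "ok",
    }
    if frame_shape is not None:
        H, W = frame_shape
        pts = np.concatenate([np.atleast_2d(p) for p in
                              out["cells"] + [out["footprint"][None]]])
        inside = (pts[:, 0] >= 0) & (pts[:, 0] < W) & (pts[:, 1] >= 0) & (pts[:, 1] < H)
        if not inside.any():
            out["status"] = "outside"
            warnings.warn("projected grid falls entirely outside the frame")
    return out


def _rasterize(polyline: np.ndarray, shape: tuple[int, int], width: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Integer pixel coordinates covered by a polyline (Bresenham, no AA)."""
    H, W = shape
    rows, cols = [], []
    pts = np.atleast_2d(np.asarray(polyline, dtype=float))
    if len(pts) == 1:
        pts = np.vstack([pts, pts])
    for p, q in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(int(round(p[1])), int(round(p[0])),
                           int(round(q[1])), int(round(q[0])))
        rows.append(rr)
        cols.append(cc)
    rr = np.concatenate(rows)
    cc = np.concatenate(cols)
    if width > 1:
        offs = np.arange(-(width // 2), width - width // 2)
        rr = (rr[:, None] + offs[None, :]).ravel()
        cc = np.repeat(cc, len(offs))
    ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
    return rr[ok], cc[ok]


def render_overlay(
    frame: np.ndarray,
    lines: list[tuple[np.ndarray, tuple[float, float, float]]],
    spec: OverlaySpec | None = None,
) -> np.ndarray:
    """Alpha-blend rasterized lines onto the frame.

    out = (1 - alpha) * frame + alpha * color on line pixels; every other
    pixel is bit-identical to the input. Grayscale frames are promoted to
    RGB by channel replication.
    """
    spec = spec or OverlaySpec()
    img = np.asarray(frame, dtype=float)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    out = img.copy()
    H, W = out.shape[:2]
    for polyline, color in lines:
        rr, cc = _rasterize(polyline, (H, W), spec.line_width)
        out[rr, cc] = (1.0 - spec.alpha) * out[rr, cc] + spec.alpha * np.asarray(color)
    return out


def overlay_frame(frame, grid, result: RegistrationResult, calib_mm_per_px,
                  extra_curves_mm=None, spec: OverlaySpec | None = None) -> np.ndarray:
    """Convenience: project the grid through a registration result and blend."""
    spec = spec or OverlaySpec()
    proj = project_grid(grid, result.transform, calib_mm_per_px,
                        extra_curves_mm=extra_curves_mm, frame_shape=frame.shape[:2])
    lines = [(c, spec.grid_color) for c in proj["cells"]]
    lines += [(b, spec.boundary_color) for b in proj["boundary"]]
    lines.append((proj["footprint"][None], spec.footprint_color))
    return render_overlay(frame, lines, spec)


@dataclass
class TrackState:
    frame_index: int
    transform: RigidTransform2D
    rmse_mm: float
    status: str
    reinit: bool


def track_frames(
    frames: list[np.ndarray],
    model_curves_mm: list[np.ndarray],
    calib_mm_per_px: float,
    init_f: RigidTransform2D | None = None,
    reinit_factor: float = 2.0,
) -> list[TrackState]:
    """Register a frame sequence with temporal seeding.

    Frame 0 (or any frame after a failure) runs the full SIFT+ICP
    registration; subsequent frames run ICP seeded with the previous
    transform. A frame whose RMSE exceeds ``reinit_factor`` times the
    running median of accepted RMSEs triggers re-initialization.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    src = np.concatenate([np.asarray(c, dtype=float) / calib_mm_per_px
                          for c in model_curves_mm])
    states: list[TrackState] = []
    prev: RigidTransform2D | None = init_f
    accepted: list[float] = []
    any_ok = False
    for k, frame in enumerate(frames):
        reinit = False
        rmse_mm = float("inf")
        status = "failed"
        T = prev
        if prev is not None:
            try:
                tgt = edge_points(detect_edges(enhance(frame)))
                if len(tgt) >= 3:
                    T = icp_refine(src, tgt, init=prev)
                    rmse_mm = T.rmse * calib_mm_per_px
                    status = "ok"
            except ValueError:
                status = "failed"
            med = float(np.median(accepted)) if accepted else None
            if status == "ok" and med is not None and rmse_mm > reinit_factor * med:
                status = "degraded"
        if prev is None or status != "ok":
            reinit = True
            res = register_frame(frame, model_curves_mm, calib_mm_per_px)
            if res.status == "ok":
                T, rmse_mm, status = res.transform, res.rmse_mm, "ok"
            else:
                T, rmse_mm, status = prev, float("inf"), "failed"
        if status == "ok":
            accepted.append(rmse_mm)
            prev = T
            any_ok = True
        states.append(TrackState(frame_index=k,
                                 transform=T if T is not None else RigidTransform2D.identity(),
                                 rmse_mm=rmse_mm, status=status, reinit=reinit))
    if not any_ok:
        raise ValueError(f"tracking failed on all {len(frames)} frames: "
                         + "; ".join(s.status for s in states))
    return states
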