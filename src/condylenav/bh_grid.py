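"""Bernard-Hertel grid construction on the lateral condylar model.

In the standard lateral view (orthographic projection along the epicondylar
axis, so the condyles overlap), Blumensaat's line B(s) is the smoothed
contour of the intercondylar roof. Two reference axes follow from it: the
deep-shallow diameter line D(t), parallel to B and spanning the
posterior-to-anterior extent of the lateral condyle, and the height line
H(h), perpendicular to B, spanning roof to the most inferior point. The
4x4 grid divides both axes into quarters, and the recommended ACL femoral
footprint sits at t = 24.8 % from the posterior margin and h = 28.5 % from
the roof.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._util import moving_average, unit
from .volume_mesh import SurfaceMesh

FOOTPRINT_T = 0.248   # fraction of D from the posterior margin
FOOTPRINT_H = 0.285   # fraction of H from the roof


@dataclass
class LateralProjection:
    """Orthographic projection along the epicondylar axis.

    2D frame: first axis ``u`` points anterior, second axis ``v`` superior;
    coordinates in mm about ``origin3d``.
    """

    direction: np.ndarray
    u: np.ndarray
    v: np.ndarray
    origin3d: np.ndarray
    points2d: np.ndarray          # projected mesh vertices

    def project(self, points: np.ndarray) -> np.ndarray:
        rel = np.asarray(points, dtype=float) - self.origin3d
        return np.stack([rel @ self.u, rel @ self.v], axis=1)

    def backproject(self, points2d: np.ndarray) -> np.ndarray:
        p = np.asarray(points2d, dtype=float)
        return self.origin3d + p[:, :1] * self.u + p[:, 1:2] * self.v


@dataclass
class BlumensaatLine:
    """Arc-length parameterized smoothed roof polyline in the lateral view."""

    points2d: np.ndarray
    s: np.ndarray                 # cumulative arc length, s[0] = 0
    direction: np.ndarray         # unit 2D principal direction, anterior(+)

    @property
    def length(self) -> float:
        return float(self.s[-1])


@dataclass
class BHGrid:
    """4x4 Bernard-Hertel grid with the recommended footprint point."""

    d_dir: np.ndarray             # unit 2D, along Blumensaat, posterior -> anterior
    h_dir: np.ndarray             # unit 2D, perpendicular, roof -> inferior
    origin2d: np.ndarray          # posterior-roof grid corner
    d_length: float
    h_length: float
    blumensaat: BlumensaatLine
    footprint2d: np.ndarray
    footprint3d: np.ndarray
    projection: LateralProjection
    cells: list[np.ndarray] = field(default_factory=list)  # grid lines, (2, 2) each

    def footprint_fractions(self) -> tuple[float, float]:
        rel = self.footprint2d - self.origin2d
        return (float(rel @ self.d_dir / self.d_length),
                float(rel @ self.h_dir / self.h_length))

    def corner(self, t: float, h: float) -> np.ndarray:
        return self.origin2d + t * self.d_length * self.d_dir + h * self.h_length * self.h_dir

    def to_json(self, path: str | Path) -> None:
        payload = {
            "d_axis": [self.corner(0, 0).tolist(), self.corner(1, 0).tolist()],
            "h_axis": [self.corner(0, 0).tolist(), self.corner(0, 1).tolist()],
            "d_length_mm": self.d_length,
            "h_length_mm": self.h_length,
            "cells": [c.tolist() for c in self.cells],
            "footprint2d_mm": self.footprint2d.tolist(),
            "footprint3d_mm": self.footprint3d.tolist(),
            "footprint_fractions": list(self.footprint_fractions()),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def lateral_projection(
    lateral_mesh: SurfaceMesh,
    axis: np.ndarray,
    anterior_hint=(0.0, 1.0, 0.0),
    superior_hint=(0.0, 0.0, 1.0),
) -> LateralProjection:
    """Project the lateral condylar mesh along the epicondylar axis."""
    a = unit(np.asarray(axis, dtype=float))
    ah = np.asarray(anterior_hint, dtype=float)
    u = ah - np.dot(ah, a) * a
    if np.linalg.norm(u) < 1e-9:
        raise ValueError("anterior hint parallel to the projection axis")
    u = unit(u)
    v = np.cross(a, u)
    if np.dot(v, np.asarray(superior_hint, dtype=float)) < 0:
        v = -v
    origin = lateral_mesh.vertices.view(np.ndarray).mean(axis=0)
    proj = LateralProjection(direction=a, u=u, v=v, origin3d=origin,
                             points2d=np.empty((0, 2)))
    proj.points2d = proj.project(lateral_mesh.vertices.view(np.ndarray))
    return proj


def blumensaat_line(
    proj: LateralProjection,
    notch_roof_pts: np.ndarray,
    smooth_window: int = 5,
) -> BlumensaatLine:
    """Smooth the projected intercondylar-roof polyline into B(s).

    The grid orientation is the first principal component of the smoothed
    points, oriented anteriorly (positive first frame axis).
    """
    pts3 = np.asarray(notch_roof_pts, dtype=float)
    if pts3.ndim != 2 or len(pts3) < 2:
        raise ValueError("roof polyline needs >= 2 points")
    p2 = pts3 if pts3.shape[1] == 2 else proj.project(pts3)
    p2 = moving_average(p2, smooth_window)
    seg = np.linalg.norm(np.diff(p2, axis=0), axis=1)
    if seg.sum() < 1e-9:
        raise ValueError("degenerate roof polyline")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    q = p2 - p2.mean(axis=0)
    _, _, vt = np.linalg.svd(q, full_matrices=False)
    d = vt[0]
    if d[0] < 0:
        d = -d
    return BlumensaatLine(points2d=p2, s=s, direction=unit(d))


def build_grid(proj: LateralProjection, B: BlumensaatLine) -> BHGrid:
    """Construct the 4x4 grid and the footprint point.

    D spans the silhouette extent along B's direction (posterior margin at
    t = 0); H spans from the roof level (the Blumensaat line's median
    offset) to the most inferior silhouette point. The footprint is placed
    at the published fractions and also back-projected to 3D.
    """
    d = unit(B.direction)
    h = np.array([d[1], -d[0]])
    if h[1] > 0:          # inferior is -v in the lateral frame
        h = -h
    sil = proj.points2d
    td = sil @ d
    t0, t1 = float(td.min()), float(td.max())
    h0 = float(np.median(B.points2d @ h))
    h1 = float((sil @ h).max())
    d_len = t1 - t0
    h_len = h1 - h0
    if d_len < 1e-9 or h_len < 1e-9:
        raise ValueError("zero-extent grid axes")
    origin = t0 * d + h0 * h
    grid = BHGrid(d_dir=d, h_dir=h, origin2d=origin, d_length=d_len,
                  h_length=h_len, blumensaat=B,
                  footprint2d=np.zeros(2), footprint3d=np.zeros(3),
                  projection=proj)
    grid.footprint2d = grid.corner(FOOTPRINT_T, FOOTPRINT_H)
    grid.footprint3d = proj.backproject(grid.footprint2d[None])[0]
    cells = []
    for k in range(5):
        f = k / 4.0
        cells.append(np.stack([grid.corner(f, 0.0), grid.corner(f, 1.0)]))
        cells.append(np.stack([grid.corner(0.0, f), grid.corner(1.0, f)]))
    grid.cells = cells
    return grid
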