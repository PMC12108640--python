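"""Initial sagittal plane from notch landmarks, and plane-mesh contours.

The initial sagittal plane passes through the anterior and posterior
intercondylar-notch landmarks and contains the transverse-plane normal, so
it divides the condyles along the notch midline while staying perpendicular
to the transverse plane. Plane-mesh intersections are returned as ordered
2D contours in a reproducible in-plane frame.
"""
from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import trimesh

from ._util import unit, orthonormal_frame
from .volume_mesh import SurfaceMesh


@dataclass
class Plane:
    """Oriented plane {p : normal . p = offset}, mm."""

    normal: np.ndarray
    offset: float

    def __post_init__(self):
        self.normal = unit(np.asarray(self.normal, dtype=float))
        self.offset = float(self.offset)

    @classmethod
    def from_point_normal(cls, point, normal) -> "Plane":
        n = unit(np.asarray(normal, dtype=float))
        return cls(normal=n, offset=float(np.dot(n, point)))

    @property
    def point(self) -> np.ndarray:
        return self.normal * self.offset

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.normal - self.offset

    def shifted(self, delta: float) -> "Plane":
        return Plane(normal=self.normal.copy(), offset=self.offset + delta)


@dataclass
class PlanarContour:
    """Ordered 2D contour in an in-plane orthonormal frame.

    ``frame`` is (origin, u, v): 3D origin and the two in-plane unit axes.
    Closed contours are counter-clockwise in (u, v) and do not repeat the
    first point.
    """

    points: np.ndarray
    frame: tuple[np.ndarray, np.ndarray, np.ndarray]
    closed: bool = False

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.closed and len(self.points) < 3:
            raise ValueError("closed contour needs >= 3 points")

    def __len__(self):
        return len(self.points)

    def to_3d(self) -> np.ndarray:
        origin, u, v = self.frame
        return origin + self.points[:, :1] * u + self.points[:, 1:2] * v

    def perimeter(self) -> float:
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    def signed_area(self) -> float:
        p = self.points
        x, y = p[:, 0], p[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def subarc(self, indices: np.ndarray) -> "PlanarContour":
        return PlanarContour(self.points[indices], self.frame, closed=False)


def initial_sagittal_plane(
    anterior_pt,
    posterior_pt,
    transverse_normal,
    medial_hint=None,
) -> Plane:
    """Sagittal plane through both notch landmarks, containing the
    transverse-plane normal direction.

    The plane normal is the cross product of the notch-line direction and
    the transverse normal; if ``medial_hint`` (a point on the medial side)
    is given the normal is oriented toward it.
    """
    a = np.asarray(anterior_pt, dtype=float)
    p = np.asarray(posterior_pt, dtype=float)
    tn = unit(np.asarray(transverse_normal, dtype=float))
    d = a - p
    if np.linalg.norm(d) < 1e-9:
        raise ValueError("notch landmarks coincide")
    n = np.cross(d, tn)
    if np.linalg.norm(n) < 1e-9 * np.linalg.norm(d):
        raise ValueError("notch line is parallel to the transverse normal")
    n = unit(n)
    plane = Plane(normal=n, offset=float(np.dot(n, a)))
    if medial_hint is not None and plane.signed_distance(np.asarray(medial_hint, float)[None])[0] < 0:
        plane = Plane(normal=-n, offset=float(np.dot(-n, a)))
    return plane


def load_landmarks(path: str | Path) -> dict:
    """Landmark JSON: anterior_notch, posterior_notch, transverse_normal (mm)."""
    d = json.loads(Path(path).read_text())
    out = {k: np.asarray(v, dtype=float) for k, v in d.items()}
    for key in ("anterior_notch", "posterior_notch", "transverse_normal"):
        if key not in out:
            raise KeyError(f"landmark file missing '{key}'")
    return out


def plane_mesh_contour(
    mesh: SurfaceMesh,
    plane: Plane,
    superior_hint=(0.0, 0.0, 1.0),
    min_points: int = 3,
) -> list[PlanarContour]:
    """All plane-mesh intersection polylines as ordered planar contours.

    The in-plane frame is fixed by projecting ``superior_hint`` onto the
    plane (first axis) with the second axis completing a right-handed frame;
    closed loops are returned counter-clockwise.
    """
    segments = trimesh.intersections.mesh_plane(
        mesh, plane_normal=plane.normal, plane_origin=plane.point)
    if len(segments) == 0:
        return []
    u, v = orthonormal_frame(plane.normal, hint=np.asarray(superior_hint, dtype=float))
    origin = plane.point
    path = trimesh.load_path(segments)
    contours: list[PlanarContour] = []
    for poly in path.discrete:
        poly = np.asarray(poly, dtype=float)
        closed = bool(np.allclose(poly[0], poly[-1], atol=1e-8))
        if closed:
            poly = poly[:-1]
        if len(poly) < min_points:
            continue
        pts2 = np.stack([(poly - origin) @ u, (poly - origin) @ v], axis=1)
        # drop consecutive duplicates
        keep = np.ones(len(pts2), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(pts2, axis=0), axis=1) > 1e-10
        pts2 = pts2[keep]
        if len(pts2) < min_points:
            continue
        c = PlanarContour(pts2, (origin, u, v), closed=closed)
        if closed and c.signed_area() < 0:
            c = PlanarContour(pts2[::-1].copy(), (origin, u, v), closed=True)
        contours.append(c)
    contours.sort(key=lambda c: -c.perimeter())
    return contours
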