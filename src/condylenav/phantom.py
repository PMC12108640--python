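"""Synthetic distal-femur phantoms with full ground truth.

The phantom emulates the anatomy the pipeline needs, in a fixed world frame:
+x points lateral (the epicondylar axis), +y anterior, +z superior.

* two ellipsoidal condylar lobes centred at ``(+-separation/2, 0, 0)``;
  the default lobes have equal y/z semi-axes so sagittal sections
  perpendicular to the epicondylar axis are exact circles — the geometric
  premise of the sagittal-plane optimization;
* a shaft stub (elliptic cylinder) joining the lobes above an oblique roof
  plane; the roof segment over the intercondylar gap plays the role of
  Blumensaat's line and its obliquity is a known knob;
* a sharp capsular-line crease carved along a circular arc that lies exactly
  on the lateral lobe surface: a ramped channel is removed medial to the
  arc, leaving a single convex ridge (positive Gaussian curvature) along
  the arc while the channel's far junction is concave and therefore ignored
  by the ridge detector.

Intensities follow a two-level model (bone 700, background 0) with optional
Gaussian noise; the matching segmentation threshold is 350.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
import trimesh

from ._util import unit, orthonormal_frame
from .volume_mesh import BinaryMask, SurfaceMesh, VolumeImage

BONE_INTENSITY = 700.0
THRESHOLD = 350.0


@dataclass(frozen=True)
class CreaseArc:
    """Circular arc (centre, radius, angular span) carrying the planted ridge.

    The arc lives in the plane through ``center`` perpendicular to
    ``normal`` (the epicondylar direction); angles are measured in that
    plane from +y toward +z, in degrees. The ridge itself is a raised bead
    (torus segment of radius ``bead_radius``) laid along the arc on the
    lobe surface — its crest is the single high-Gaussian-curvature line the
    feature extractor must recover, and its junctions with the lobe are
    concave, so they cannot masquerade as the ridge. The bead tapers to
    nothing over ``taper_deg`` at each end so the ridge terminates cleanly.
    """

    center: tuple[float, float, float]
    radius: float
    span_deg: tuple[float, float] = (160.0, 300.0)
    bead_radius: float = 1.0
    taper_deg: float = 12.0
    normal: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self):
        if self.radius <= 0 or self.bead_radius <= 0:
            raise ValueError("arc and bead radii must be positive")
        lo, hi = self.span_deg
        span = hi - lo
        if not (0.0 < span <= 180.0):
            raise ValueError("angular span must be in (0, 180] degrees")
        if not (0.0 <= lo < hi <= 360.0):
            raise ValueError("span angles must satisfy 0 <= start < end <= 360")
        if not (0.0 <= self.taper_deg < span / 2.0):
            raise ValueError("taper must be shorter than half the span")

    @property
    def core_span_deg(self) -> tuple[float, float]:
        """Angular span of the full-height (untapered) ridge crest."""
        return (self.span_deg[0] + self.taper_deg, self.span_deg[1] - self.taper_deg)

    def sample(self, n: int = 80, core_only: bool = False) -> np.ndarray:
        """Points along the construction arc (mm), ordered by angle."""
        lo, hi = self.core_span_deg if core_only else self.span_deg
        th = np.deg2rad(np.linspace(lo, hi, n))
        c = np.asarray(self.center, dtype=float)
        # in-plane axes: y and z of the world frame (normal is +-x by default)
        nrm = unit(np.asarray(self.normal))
        u, v = orthonormal_frame(nrm, hint=(0.0, 1.0, 0.0))
        return c + self.radius * (np.cos(th)[:, None] * u + np.sin(th)[:, None] * v)


@dataclass(frozen=True)
class PhantomSpec:
    """Construction parameters of the synthetic distal femur (mm)."""

    condyle_radii_medial: tuple[float, float, float] = (16.0, 24.0, 24.0)
    condyle_radii_lateral: tuple[float, float, float] = (15.0, 22.0, 22.0)
    condyle_separation: float = 46.0
    notch_depth: float = 8.0
    roof_slope: float = 0.15
    crease_arc: CreaseArc | None = None
    voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    noise_sd: float = 30.0
    seed: int = 0
    margin: float = 3.0

    def __post_init__(self):
        for r in (*self.condyle_radii_medial, *self.condyle_radii_lateral,
                  *self.voxel_spacing, self.condyle_separation):
            if r <= 0:
                raise ValueError("radii, separation and spacing must be positive")
        if self.crease_arc is None:
            object.__setattr__(self, "crease_arc", self.default_crease_arc())

    def default_crease_arc(self) -> CreaseArc:
        """Arc on the medial aspect of the lateral lobe, exactly on its surface.

        Requires equal y/z semi-axes of the lateral lobe (circular sagittal
        cross-sections), which the defaults guarantee.
        """
        rx, ry, rz = self.condyle_radii_lateral
        if abs(ry - rz) > 1e-9:
            raise ValueError("default crease arc needs equal y/z lateral radii")
        cx = self.condyle_separation / 2.0
        x0 = cx - 0.5 * rx  # half a semi-axis medial of the lobe centre
        radius = ry * float(np.sqrt(1.0 - ((x0 - cx) / rx) ** 2))
        return CreaseArc(center=(x0, 0.0, 0.0), radius=radius)

    @property
    def lateral_center(self) -> np.ndarray:
        return np.array([self.condyle_separation / 2.0, 0.0, 0.0])

    @property
    def medial_center(self) -> np.ndarray:
        return np.array([-self.condyle_separation / 2.0, 0.0, 0.0])


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom (all mm)."""

    epicondylar_axis: np.ndarray
    notch_anterior_pt: np.ndarray
    notch_posterior_pt: np.ndarray
    crease_polyline: np.ndarray
    blumensaat_polyline: np.ndarray
    footprint_pt: np.ndarray
    lateral_marker_pt: np.ndarray
    threshold: float = THRESHOLD

    def to_json(self, path: str | Path) -> None:
        def ser(v):
            return np.asarray(v).tolist()
        payload = {
            "epicondylar_axis": ser(self.epicondylar_axis),
            "notch_anterior_pt": ser(self.notch_anterior_pt),
            "notch_posterior_pt": ser(self.notch_posterior_pt),
            "crease_polyline": ser(self.crease_polyline),
            "blumensaat_polyline": ser(self.blumensaat_polyline),
            "footprint_pt": ser(self.footprint_pt),
            "lateral_marker_pt": ser(self.lateral_marker_pt),
            "threshold": self.threshold,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            epicondylar_axis=np.array(d["epicondylar_axis"]),
            notch_anterior_pt=np.array(d["notch_anterior_pt"]),
            notch_posterior_pt=np.array(d["notch_posterior_pt"]),
            crease_polyline=np.array(d["crease_polyline"]),
            blumensaat_polyline=np.array(d["blumensaat_polyline"]),
            footprint_pt=np.array(d["footprint_pt"]),
            lateral_marker_pt=np.array(d["lateral_marker_pt"]),
            threshold=float(d.get("threshold", THRESHOLD)),
        )


# ---------------------------------------------------------------------------
# solid construction


def _shaft_params(spec: PhantomSpec):
    sx = spec.condyle_separation / 2.0 + 2.0
    sy = 0.55 * max(spec.condyle_radii_medial[1], spec.condyle_radii_lateral[1])
    z_top = max(spec.condyle_radii_medial[2], spec.condyle_radii_lateral[2]) + 6.0
    return sx, sy, z_top


def _smin(a, b, k):
    """Exponential smooth minimum: fillets the union junction within ~k mm."""
    return -k * np.logaddexp(-a / k, -b / k)


def _smax(a, b, k):
    return k * np.logaddexp(a / k, b / k)


def _solid_indicator(spec: PhantomSpec, x, y, z, blend: float = 2.5):
    """Boolean solid on broadcastable world-coordinate grids.

    The lobes and shaft are combined through smooth-blended quasi-signed
    distance fields so the shaft-condyle welds are filleted (no spurious
    sharp ridges competing with the planted crease); the crease channel is
    the only sharp boolean feature.
    """
    mrx, mry, mrz = spec.condyle_radii_medial
    lrx, lry, lrz = spec.condyle_radii_lateral
    mc, lc = spec.medial_center, spec.lateral_center

    def ellipsoid_sdf(center, radii):
        rx_, ry_, rz_ = radii
        q = np.sqrt(((x - center[0]) / rx_) ** 2 + ((y - center[1]) / ry_) ** 2
                    + ((z - center[2]) / rz_) ** 2)
        return (q - 1.0) * min(radii)

    d_med = ellipsoid_sdf(mc, spec.condyle_radii_medial)
    d_lat = ellipsoid_sdf(lc, spec.condyle_radii_lateral)

    sx, sy, z_top = _shaft_params(spec)
    d_xy = (np.sqrt((x / sx) ** 2 + (y / sy) ** 2) - 1.0) * min(sx, sy)
    roof = spec.notch_depth + spec.roof_slope * y
    d_shaft = np.maximum(_smax(d_xy, roof - z, blend), z - z_top)

    sdf = _smin(d_med, _smin(d_lat, d_shaft, blend), blend)

    arc = spec.crease_arc
    cx = np.asarray(arc.center, dtype=float)
    # raised bead along the arc: points within bead_radius of the arc
    # circle, with the radius tapering to zero near the span ends
    radial = np.sqrt((y - cx[1]) ** 2 + (z - cx[2]) ** 2)
    d_circle = np.sqrt((radial - arc.radius) ** 2 + (x - cx[0]) ** 2)
    theta = np.degrees(np.arctan2(z - cx[2], y - cx[1])) % 360.0
    lo, hi = arc.span_deg
    # distance (deg) into the span from each end, negative outside
    into = np.minimum(theta - lo, hi - theta)
    if arc.taper_deg > 0:
        factor = np.clip(into / arc.taper_deg, 0.0, 1.0)
    else:
        factor = (into >= 0).astype(float)
    bead = (into >= 0.0) & (d_circle <= arc.bead_radius * factor)
    return (sdf < 0.0) | bead


def _analytic_footprint(spec: PhantomSpec) -> np.ndarray:
    """Grid-rule footprint computed from the analytic lateral silhouette.

    Projects the lateral portion (lateral lobe + shaft) along +x onto the
    (y, z) plane and applies the 24.8 % / 28.5 % fractions relative to the
    planted roof line, without touching any mesh machinery.
    """
    lrx, lry, lrz = spec.condyle_radii_lateral
    sx, sy, z_top = _shaft_params(spec)
    th = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    lobe = np.stack([lry * np.cos(th), lrz * np.sin(th)], axis=1)
    ys = np.linspace(-sy, sy, 121)
    shaft_pts = [np.stack([ys, np.full_like(ys, z_top)], axis=1)]
    for sgn in (-1.0, 1.0):
        zs = np.linspace(spec.notch_depth + spec.roof_slope * sgn * sy, z_top, 50)
        shaft_pts.append(np.stack([np.full_like(zs, sgn * sy), zs], axis=1))
    sil = np.concatenate([lobe] + shaft_pts, axis=0)

    d = unit(np.array([1.0, spec.roof_slope]))       # along the roof, anterior
    h = np.array([d[1], -d[0]])                      # perpendicular, inferior
    t = sil @ d
    t0, t1 = t.min(), t.max()
    roof_pt = np.array([0.0, spec.notch_depth])
    h0 = roof_pt @ h
    h1 = (sil @ h).max()
    p2 = (t0 + 0.248 * (t1 - t0)) * d + (h0 + 0.285 * (h1 - h0)) * h
    return np.array([spec.condyle_separation / 2.0, p2[0], p2[1]])


def make_femur_phantom(spec: PhantomSpec) -> tuple[VolumeImage, PhantomTruth]:
    """Generate the voxel phantom and its ground truth.

    Deterministic: identical (spec, seed) pairs give bit-identical volumes.
    """
    mrx, mry, mrz = spec.condyle_radii_medial
    lrx, lry, lrz = spec.condyle_radii_lateral
    sx, sy, z_top = _shaft_params(spec)
    m = spec.margin
    lo = np.array([-spec.condyle_separation / 2.0 - mrx - m,
                   -max(mry, lry) - m,
                   -max(mrz, lrz) - m])
    hi = np.array([spec.condyle_separation / 2.0 + lrx + m,
                   max(mry, lry) + m,
                   z_top + m])
    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    if np.any(shape < 8):
        raise ValueError("lobes do not overlap the volume bounds")
    xs = lo[0] + spacing[0] * np.arange(shape[0])
    ys = lo[1] + spacing[1] * np.arange(shape[1])
    zs = lo[2] + spacing[2] * np.arange(shape[2])
    x = xs[:, None, None]
    y = ys[None, :, None]
    z = zs[None, None, :]
    solid = _solid_indicator(spec, x, y, z)
    if not solid.any():
        raise ValueError("phantom solid is empty inside the volume bounds")

    vox = solid.astype(np.float32) * BONE_INTENSITY
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vox = vox + rng.normal(0.0, spec.noise_sd, size=vox.shape).astype(np.float32)
    volume = VolumeImage(vox, spacing=spacing, origin=lo)

    # ground truth -----------------------------------------------------
    gap_y = 0.92 * sy
    yy = np.linspace(-gap_y, gap_y, 41)
    roofline = np.stack([np.zeros_like(yy), yy, spec.notch_depth + spec.roof_slope * yy], axis=1)
    truth = PhantomTruth(
        epicondylar_axis=np.array([1.0, 0.0, 0.0]),
        notch_anterior_pt=roofline[-1],
        notch_posterior_pt=roofline[0],
        crease_polyline=_crease_crest(spec),
        blumensaat_polyline=roofline,
        footprint_pt=_analytic_footprint(spec),
        lateral_marker_pt=spec.lateral_center,
    )
    return volume, truth


def _crease_crest(spec: PhantomSpec, n: int = 80) -> np.ndarray:
    """Crest line of the planted bead: the core arc pushed outward along
    the lateral lobe's surface normal by the bead radius."""
    arc = spec.crease_arc
    base = arc.sample(n, core_only=True)
    lrx, lry, lrz = spec.condyle_radii_lateral
    lc = spec.lateral_center
    grad = (base - lc) / np.array([lrx ** 2, lry ** 2, lrz ** 2])
    nrm = grad / np.linalg.norm(grad, axis=1, keepdims=True)
    return base + arc.bead_radius * nrm


def make_mesh_phantom(
    spec: PhantomSpec | None = None,
    subdivisions: int = 4,
    transform: np.ndarray | None = None,
    include_shaft: bool = False,
) -> tuple[SurfaceMesh, np.ndarray]:
    """Analytic two-lobe mesh phantom (exact ellipsoid meshes, no voxels).

    Used when discretization-free geometry is needed (e.g. sub-degree
    plane-recovery properties). Returns (mesh, epicondylar_axis); if a 4x4
    rigid ``transform`` is given both are moved by it.
    """
    spec = spec or PhantomSpec()
    parts = []
    for center, radii in ((spec.medial_center, spec.condyle_radii_medial),
                          (spec.lateral_center, spec.condyle_radii_lateral)):
        s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
        s.apply_scale(radii)
        s.apply_translation(center)
        parts.append(s)
    if include_shaft:
        sx, sy, z_top = _shaft_params(spec)
        box = trimesh.creation.box(extents=(2 * sx, 2 * sy, z_top - spec.notch_depth))
        box.apply_translation((0, 0, (z_top + spec.notch_depth) / 2.0))
        parts.append(box)
    mesh = trimesh.util.concatenate(parts)
    axis = np.array([1.0, 0.0, 0.0])
    if transform is not None:
        mesh.apply_transform(transform)
        axis = transform[:3, :3] @ axis
    return mesh, axis


# ---------------------------------------------------------------------------
# rendering


@dataclass
class CameraModel:
    """Pinhole camera; image origin top-left, x right, y down (pixels)."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    R: np.ndarray = field(default_factory=lambda: np.eye(3))  # world -> camera
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @classmethod
    def look_at(cls, eye, target, up=(0.0, 0.0, 1.0), fx=400.0, fy=400.0,
                width=256, height=256) -> "CameraModel":
        eye = np.asarray(eye, dtype=float)
        fwd = unit(np.asarray(target, dtype=float) - eye)          # camera +z
        right = unit(np.cross(fwd, np.asarray(up, dtype=float)))   # camera +x
        down = np.cross(fwd, right)                                # camera +y
        R = np.stack([right, down, fwd])
        return cls(fx=fx, fy=fy, cx=width / 2.0, cy=height / 2.0,
                   width=width, height=height, R=R, t=-R @ eye)

    def to_camera(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.R.T + self.t

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pixel coordinates (x, y) and camera-frame depths."""
        pc = self.to_camera(points)
        z = pc[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            u = self.fx * pc[:, 0] / z + self.cx
            v = self.fy * pc[:, 1] / z + self.cy
        return np.stack([u, v], axis=1), z


def render_arthro_frame(
    mesh: SurfaceMesh,
    camera: CameraModel,
    truth: PhantomTruth | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    shading_power: float = 2.0,
    crease_albedo: float = 1.0,
    crease_halo_mm: float = 0.5,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Grayscale frame: vertex-splat z-buffer + headlight Lambertian shading.

    Vertices are z-buffered into the pixel grid, per-vertex |n.view|^power
    shading is splatted for the visible ones, holes inside the silhouette
    are filled from the nearest splat and the map lightly smoothed. When
    ``truth`` is given, vertices within ``crease_halo_mm`` of the capsular
    line are brightened by ``crease_albedo`` — emulating the whitish tissue
    of the capsular attachment, which in real arthroscopy is an albedo
    contrast, not a purely geometric one — and the exact pinhole projection
    of the crease polyline is returned, culled to visible (depth-consistent,
    in-frame) points.
    """
    H, W = camera.height, camera.width
    px, z = camera.project(mesh.vertices)
    ok = (z > 1e-6) & (px[:, 0] >= 0) & (px[:, 0] < W) & (px[:, 1] >= 0) & (px[:, 1] < H)
    if not ok.any():
        raise ValueError("camera frustum contains no part of the mesh")
    iu = px[ok, 0].astype(int)
    iv = px[ok, 1].astype(int)
    depth = np.full((H, W), np.inf)
    np.minimum.at(depth, (iv, iu), z[ok])

    splat = np.isfinite(depth)
    sil = ndi.binary_closing(splat, structure=np.ones((7, 7)))
    sil = ndi.binary_opening(sil, structure=np.ones((3, 3)))

    # Lambertian shading: headlight at the camera, per-vertex n . view,
    # splatted for depth-visible vertices and averaged per pixel
    normals = mesh.vertex_normals.view(np.ndarray)
    view = mesh.vertices.view(np.ndarray) - (-camera.R.T @ camera.t)
    view = view / np.linalg.norm(view, axis=1, keepdims=True)
    lam = np.abs((normals * view).sum(axis=1)) ** shading_power
    if truth is not None and crease_albedo != 0.0:
        from scipy.spatial import cKDTree
        dcrease, _ = cKDTree(truth.crease_polyline).query(mesh.vertices.view(np.ndarray))
        halo = np.exp(-(dcrease / crease_halo_mm) ** 2)
        lam = np.clip(lam * (1.0 + crease_albedo * halo), 0.0, 1.0)
    vis = ok.copy()
    vis[ok] &= z[ok] <= depth[iv, iu] + 1.0
    ju = px[vis, 0].astype(int)
    jv = px[vis, 1].astype(int)
    acc = np.zeros((H, W))
    cnt = np.zeros((H, W))
    np.add.at(acc, (jv, ju), lam[vis])
    np.add.at(cnt, (jv, ju), 1.0)
    has = cnt > 0
    shade_map = np.zeros((H, W))
    shade_map[has] = acc[has] / cnt[has]
    holes = sil & ~has
    if holes.any():
        _, (ri, ci) = ndi.distance_transform_edt(~has, return_indices=True)
        shade_map[holes] = shade_map[ri[holes], ci[holes]]
    shade_map = ndi.median_filter(shade_map, size=3)
    shade_map = ndi.gaussian_filter(shade_map * sil, 1.5)
    norm = ndi.gaussian_filter(sil.astype(float), 1.5)
    with np.errstate(invalid="ignore", divide="ignore"):
        shade_map = np.where(sil, shade_map / np.maximum(norm, 1e-9), 0.0)
    shade = np.where(sil, 0.15 + 0.85 * shade_map, 0.0)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        shade = np.clip(shade + rng.normal(0.0, noise_sd, shade.shape), 0.0, 1.0)
    frame = shade.astype(np.float64)

    projected_crease = None
    if truth is not None:
        cpx, cz = camera.project(truth.crease_polyline)
        keep = (cz > 1e-6) & (cpx[:, 0] >= 0) & (cpx[:, 0] < W) \
            & (cpx[:, 1] >= 0) & (cpx[:, 1] < H)
        vis = keep.copy()
        idx = np.where(keep)[0]
        for i in idx:
            u_, v_ = int(cpx[i, 0]), int(cpx[i, 1])
            if np.isfinite(depth[v_, u_]) and cz[i] > depth[v_, u_] + 3.0:
                vis[i] = False  # occluded behind the rendered surface
        projected_crease = cpx[vis]
    return frame, projected_crease
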