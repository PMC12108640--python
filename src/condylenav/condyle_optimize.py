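"""Sagittal-profile analysis and cutting-plane optimization.

The condylar articular surface is nearly circular in a true sagittal
section. Sections cut by a plane that is tilted relative to the
perpendicular of the epicondylar axis become elliptical, and the foci of
ellipses fitted to a stack of parallel sections disperse. The optimal
sagittal orientation is therefore found by minimizing a combination of the
mean sectional eccentricity and the focal dispersion over parallel sections
of both condyles, by deterministic coordinate descent on the two spherical
angles of the plane normal with step halving.

Curvature of planar contours:
    kappa(t) = (x' y'' - y' x'') / (x'^2 + y'^2)^(3/2)
with derivatives taken by centred finite differences on the arc-length
parameterization. Ellipses are fitted with the direct constrained
least-squares conic fit (B^2 - 4AC < 0 built into the solution).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import unit, orthonormal_frame
from .sagittal_frame import Plane, PlanarContour, plane_mesh_contour
from .volume_mesh import SurfaceMesh


@dataclass
class EllipseFit:
    """Conic coefficients (A..F) and derived ellipse parameters (mm)."""

    coeffs: np.ndarray
    center: np.ndarray
    semi_axes: tuple[float, float]      # (a, b), a >= b
    angle: float                        # major-axis angle, rad
    foci: np.ndarray                    # (2, 2)
    eccentricity: float
    residual_rms: float


@dataclass
class PlaneObjective:
    mean_eccentricity: float
    focal_dispersion: float
    per_section: list[EllipseFit]
    scale: float = 1.0
    weight_lambda: float = 1.0

    @property
    def value(self) -> float:
        return self.mean_eccentricity + self.weight_lambda * self.focal_dispersion / self.scale


@dataclass
class OptimizeConfig:
    n_sections_per_condyle: int = 5
    section_spacing: float = 2.0
    angle_step_init: float = 2.0        # degrees
    tol: float = 1e-4
    max_iter: int = 60
    weight_lambda: float = 1.0
    use_articular_arc: bool = True
    min_step_frac: float = 1.0 / 64.0   # stop once the step shrinks this far

    def __post_init__(self):
        if self.n_sections_per_condyle < 1 or self.section_spacing <= 0:
            raise ValueError("section counts and spacing must be positive")
        if self.angle_step_init <= 0 or self.max_iter < 1:
            raise ValueError("angle step and max_iter must be positive")


# ---------------------------------------------------------------------------
# contour curvature and articular-arc selection


def contour_curvature(contour: PlanarContour) -> np.ndarray:
    """Signed curvature (1/mm) per contour point.

    Counter-clockwise closed convex contours get positive curvature.
    Derivatives are centred finite differences on arc length (periodic for
    closed contours).
    """
    pts = contour.points
    if len(pts) < 5:
        raise ValueError("need >= 5 points for curvature estimation")
    if contour.closed:
        ext = np.vstack([pts[-2:], pts, pts[:2]])
    else:
        ext = pts
    seg = np.linalg.norm(np.diff(ext, axis=0), axis=1)
    if np.any(seg < 1e-12):
        raise ValueError("stationary points in contour")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    dx = np.gradient(ext[:, 0], s)
    dy = np.gradient(ext[:, 1], s)
    ddx = np.gradient(dx, s)
    ddy = np.gradient(dy, s)
    speed2 = dx ** 2 + dy ** 2
    if np.any(speed2 < 1e-18):
        raise ValueError("stationary points in contour")
    kappa = (dx * ddy - dy * ddx) / speed2 ** 1.5
    if contour.closed:
        kappa = kappa[2:-2]
    return kappa


def articular_region(
    contour: PlanarContour,
    curvature: np.ndarray | None = None,
    window_frac: float = 0.4,
    k_sigma: float = 3.0,
    rel_tol: float = 0.15,
) -> PlanarContour:
    """Near-circular articular arc of a closed condylar contour.

    Anchored at the curvature maximum (the prominent articular portion), the
    sliding window of ``window_frac`` of the arc length with minimal
    curvature variance is selected and extended while neighbouring points
    stay within ``max(k_sigma * window SD, rel_tol * |window mean|)`` of the
    window mean curvature. A fully uniform contour (e.g. a circle) is
    returned whole.
    """
    if not contour.closed:
        raise ValueError("articular_region expects a closed contour")
    if curvature is None:
        curvature = contour_curvature(contour)
    kappa = np.asarray(curvature, dtype=float)
    n = len(kappa)
    if n < 8:
        raise ValueError("contour too short")
    # light smoothing for the anchor only
    win = max(3, n // 40)
    kernel = np.ones(win) / win
    ksm = np.convolve(np.concatenate([kappa[-win:], kappa, kappa[:win]]), kernel, "same")[win:-win]
    anchor = int(np.argmax(ksm))

    w = max(5, int(round(window_frac * n)))
    # windows (cyclic) containing the anchor
    best = None
    for start in range(anchor - w + 1, anchor + 1):
        idx = np.arange(start, start + w) % n
        var = float(np.var(kappa[idx]))
        if best is None or var < best[0]:
            best = (var, start)
    _, start = best
    idx = np.arange(start, start + w) % n
    mu = float(np.mean(kappa[idx]))
    sd = float(np.std(kappa[idx]))
    tol = max(k_sigma * sd, rel_tol * abs(mu), 1e-12)

    lo, hi = start, start + w - 1  # inclusive, cyclic indices
    while hi - lo + 1 < n and abs(kappa[(hi + 1) % n] - mu) <= tol:
        hi += 1
    while hi - lo + 1 < n and abs(kappa[(lo - 1) % n] - mu) <= tol:
        lo -= 1
    length = hi - lo + 1
    if length >= n:
        return contour
    indices = np.arange(lo, hi + 1) % n
    if len(indices) < 5:
        raise ValueError("no qualifying articular arc")
    return contour.subarc(indices)


# ---------------------------------------------------------------------------
# constrained ellipse fitting (direct least squares)


def fit_ellipse(points: np.ndarray) -> EllipseFit:
    """Direct constrained least-squares conic fit.

    Solves the generalized eigenproblem of the design scatter matrix with
    the ellipse constraint 4AC - B^2 = 1 built in (numerically stable split
    formulation), then derives centre, semi-axes, foci and eccentricity.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 6:
        raise ValueError("need >= 6 two-dimensional points")
    mean = pts.mean(axis=0)
    scale = float(np.sqrt(((pts - mean) ** 2).sum(axis=1).mean()))
    if scale < 1e-12:
        raise ValueError("degenerate point set")
    q = (pts - mean) / scale
    x, y = q[:, 0], q[:, 1]

    D1 = np.stack([x ** 2, x * y, y ** 2], axis=1)
    D2 = np.stack([x, y, np.ones_like(x)], axis=1)
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError("collinear or degenerate points") from exc
    M = S1 + S2 @ T
    C = np.array([[0.0, 0.0, 2.0], [0.0, -1.0, 0.0], [2.0, 0.0, 0.0]])
    try:
        evals, evecs = np.linalg.eig(np.linalg.solve(C, M))
    except np.linalg.LinAlgError as exc:
        raise ValueError("ellipse fit failed") from exc
    cond = 4 * evecs[0] * evecs[2] - evecs[1] ** 2
    ok = np.isreal(evals) & (cond > 1e-12)
    if not ok.any():
        raise ValueError("no elliptical solution (points may be collinear)")
    a1 = np.real(evecs[:, np.where(ok)[0][0]])
    coeffs_n = np.concatenate([a1, T @ a1])

    # un-normalize: substitute q = (p - mean) / scale into the fitted conic
    An, Bn, Cn, Dn, En, Fn = coeffs_n
    s = 1.0 / scale
    mx, my = mean
    coeffs = np.array([
        An * s ** 2,
        Bn * s ** 2,
        Cn * s ** 2,
        -2 * An * s ** 2 * mx - Bn * s ** 2 * my + Dn * s,
        -Bn * s ** 2 * mx - 2 * Cn * s ** 2 * my + En * s,
        An * s ** 2 * mx ** 2 + Bn * s ** 2 * mx * my + Cn * s ** 2 * my ** 2
        - Dn * s * mx - En * s * my + Fn,
    ])
    return _ellipse_params(coeffs, pts)


def _ellipse_params(coeffs: np.ndarray, pts: np.ndarray) -> EllipseFit:
    A, B, C, D, E, F = coeffs
    disc = B ** 2 - 4 * A * C
    if disc >= 0:
        raise ValueError("conic is not an ellipse")
    cx = (2 * C * D - B * E) / disc
    cy = (2 * A * E - B * D) / disc
    # sign convention: quadratic part positive definite, so -F(center) > 0
    if A + C < 0:
        coeffs = -coeffs
        A, B, C, D, E, F = coeffs
    M = np.array([[A, B / 2.0], [B / 2.0, C]])
    evals, evecs = np.linalg.eigh(M)
    Fc = A * cx ** 2 + B * cx * cy + C * cy ** 2 + D * cx + E * cy + F
    if Fc >= 0 or np.any(evals <= 0):
        raise ValueError("conic is not a real ellipse")
    axes2 = -Fc / evals
    if np.any(axes2 <= 0):
        raise ValueError("conic is not an ellipse")
    axes = np.sqrt(axes2)
    order = np.argsort(axes)[::-1]
    a, b = float(axes[order[0]]), float(axes[order[1]])
    major = evecs[:, order[0]]
    angle = float(np.arctan2(major[1], major[0]))
    ecc = float(np.sqrt(max(0.0, 1.0 - (b * b) / (a * a))))
    c_f = a * ecc
    center = np.array([cx, cy])
    foci = np.stack([center + c_f * major, center - c_f * major])

    # Sampson-normalized algebraic residual (approximate orthogonal distance)
    x, y = pts[:, 0], pts[:, 1]
    alg = A * x ** 2 + B * x * y + C * y ** 2 + D * x + E * y + F
    gx = 2 * A * x + B * y + D
    gy = B * x + 2 * C * y + E
    gn = np.hypot(gx, gy)
    res = alg / np.maximum(gn, 1e-12)
    return EllipseFit(coeffs=coeffs, center=center, semi_axes=(a, b), angle=angle,
                      foci=foci, eccentricity=ecc,
                      residual_rms=float(np.sqrt(np.mean(res ** 2))))


# ---------------------------------------------------------------------------
# section series and the plane objective


def section_series(
    mesh: SurfaceMesh,
    plane: Plane,
    n: int,
    spacing: float,
    side: str,
    edge_margin: float | None = None,
) -> list[PlanarContour]:
    """Largest contour on each of n parallel planes offset into one condyle.

    The plane normal is taken to point toward the *lateral* side; offsets
    step inward from the outermost extent of the requested condyle. Planes
    that miss the mesh simply yield no contour (result may be shorter than
    ``n``).
    """
    if n < 1:
        raise ValueError("n >= 1 required")
    if side not in ("medial", "lateral"):
        raise ValueError("side must be 'medial' or 'lateral'")
    d = plane.signed_distance(mesh.vertices)
    if edge_margin is None:
        edge_margin = spacing
    contours: list[PlanarContour] = []
    if side == "lateral":
        start = float(d.max()) - edge_margin
        offsets = [start - spacing * k for k in range(n)]
    else:
        start = float(d.min()) + edge_margin
        offsets = [start + spacing * k for k in range(n)]
    for off in offsets:
        sec = plane_mesh_contour(mesh, plane.shifted(off))
        closed = [c for c in sec if c.closed]
        pool = closed or sec
        if pool:
            contours.append(max(pool, key=lambda c: c.perimeter()))
    return contours


def plane_objective(
    sections_medial: list[PlanarContour],
    sections_lateral: list[PlanarContour],
    weight_lambda: float = 1.0,
    use_articular_arc: bool = True,
) -> PlaneObjective:
    """Mean eccentricity and focal dispersion of fitted sectional ellipses.

    Ellipses are fitted to the articular arc of each section. Because all
    section frames share in-plane axes, fitted foci live in a common plane
    parallel to the sections; the dispersion is the RMS distance of foci to
    their own condyle's focus centroid, pooled over both condyles. The
    scalar objective is mean_eccentricity + lambda * dispersion / scale
    where scale is the mean fitted major diameter.
    """
    fits: list[EllipseFit] = []
    sq_dists: list[float] = []
    for side in (sections_medial, sections_lateral):
        side_fits = []
        for c in side:
            try:
                arc = articular_region(c) if (use_articular_arc and c.closed) else c
                side_fits.append(fit_ellipse(arc.points))
            except ValueError:
                continue
        if side_fits:
            foci = np.concatenate([f.foci for f in side_fits])
            centroid = foci.mean(axis=0)
            sq_dists.extend(((foci - centroid) ** 2).sum(axis=1).tolist())
        fits.extend(side_fits)
    if not fits:
        raise ValueError("no section could be fitted")
    mean_ecc = float(np.mean([f.eccentricity for f in fits]))
    dispersion = float(np.sqrt(np.mean(sq_dists))) if sq_dists else 0.0
    scale = float(np.mean([2 * f.semi_axes[0] for f in fits]))
    return PlaneObjective(mean_eccentricity=mean_ecc, focal_dispersion=dispersion,
                          per_section=fits, scale=scale, weight_lambda=weight_lambda)


# ---------------------------------------------------------------------------
# cutting-plane optimization


def _evaluate_plane(mesh, plane, cfg) -> PlaneObjective | None:
    med = section_series(mesh, plane, cfg.n_sections_per_condyle,
                         cfg.section_spacing, "medial")
    lat = section_series(mesh, plane, cfg.n_sections_per_condyle,
                         cfg.section_spacing, "lateral")
    if not med or not lat:
        return None
    try:
        return plane_objective(med, lat, cfg.weight_lambda, cfg.use_articular_arc)
    except ValueError:
        return None


def optimize_cutting_plane(
    mesh: SurfaceMesh,
    init: Plane,
    cfg: OptimizeConfig | None = None,
) -> tuple[Plane, PlaneObjective, list[float]]:
    """Greedy coordinate descent on the plane-normal spherical angles.

    At each iteration the four single-angle moves of the current step size
    are evaluated; the best improving move is accepted, otherwise the step
    is halved. Stops when the accepted objective change falls below
    ``cfg.tol``, the step underflows, or ``max_iter`` is reached. The plane
    pivots about the initial plane's anchor point. The trace of accepted
    objective values is non-increasing by construction.
    """
    cfg = cfg or OptimizeConfig()
    e1, e2 = orthonormal_frame(init.normal)
    p0 = init.point

    def normal_of(alpha: float, beta: float) -> np.ndarray:
        n = init.normal + np.tan(np.deg2rad(alpha)) * e1 + np.tan(np.deg2rad(beta)) * e2
        return unit(n)

    def plane_of(alpha: float, beta: float) -> Plane:
        return Plane.from_point_normal(p0, normal_of(alpha, beta))

    a = b = 0.0
    cur = _evaluate_plane(mesh, plane_of(a, b), cfg)
    if cur is None:
        raise ValueError("objective not computable for the initial plane")
    trace = [cur.value]
    step = cfg.angle_step_init
    min_step = cfg.angle_step_init * cfg.min_step_frac
    for _ in range(cfg.max_iter):
        best = None
        for da, db in ((step, 0.0), (-step, 0.0), (0.0, step), (0.0, -step)):
            obj = _evaluate_plane(mesh, plane_of(a + da, b + db), cfg)
            if obj is None:
                continue
            if obj.value < cur.value and (best is None or obj.value < best[0].value):
                best = (obj, a + da, b + db)
        if best is None:
            step *= 0.5
            if step < min_step:
                break
            continue
        change = cur.value - best[0].value
        cur, a, b = best
        trace.append(cur.value)
        if change < cfg.tol:
            break
    return plane_of(a, b), cur, trace


# ---------------------------------------------------------------------------
# virtual resection


def _boundary_loops(mesh: SurfaceMesh, plane: Plane) -> list[np.ndarray]:
    """Boundary-vertex loops of an open mesh, ordered by angle in the plane.

    Boundary vertices (on edges used by exactly one face) are grouped into
    connected components and each component is sorted by polar angle about
    its centroid in the cut-plane frame — valid for the star-shaped
    cross-sections produced by condylar cuts.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    edges = mesh.edges_sorted
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    bnd = uniq[counts == 1]
    if len(bnd) == 0:
        return []
    vids = np.unique(bnd)
    remap = {v: i for i, v in enumerate(vids)}
    rows = [remap[i] for i in bnd[:, 0]]
    cols = [remap[j] for j in bnd[:, 1]]
    g = coo_matrix((np.ones(len(bnd)), (rows, cols)), shape=(len(vids),) * 2)
    n_comp, labels = connected_components(g, directed=False)
    u, v = orthonormal_frame(plane.normal)
    loops = []
    for comp in range(n_comp):
        ids = vids[labels == comp]
        if len(ids) < 3:
            continue
        pts = mesh.vertices[ids]
        p2 = np.stack([(pts - pts.mean(axis=0)) @ u, (pts - pts.mean(axis=0)) @ v], axis=1)
        order = np.argsort(np.arctan2(p2[:, 1], p2[:, 0]))
        loops.append(ids[order])
    return loops


def resect_medial(
    mesh: SurfaceMesh,
    plane: Plane,
    lateral_marker,
) -> SurfaceMesh:
    """Cut the mesh at the plane, keeping the lateral-marker side, capped.

    Cap faces are centroid-fan triangulations of the cut boundary loops
    (valid for the star-shaped condylar cross-sections handled here). If the
    plane misses the mesh and the whole mesh is on the marker side, the mesh
    is returned unchanged.
    """
    import trimesh

    marker = np.asarray(lateral_marker, dtype=float)
    md = float(plane.signed_distance(marker[None])[0])
    if abs(md) < 1e-9:
        raise ValueError("lateral marker lies on the cutting plane")
    sign = 1.0 if md > 0 else -1.0
    d = plane.signed_distance(mesh.vertices) * sign
    if d.min() >= -1e-9:
        return mesh
    if d.max() <= 1e-9:
        raise ValueError("entire mesh is on the medial side of the plane")
    kept = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=sign * plane.normal, plane_origin=plane.point, cap=False)
    kept = trimesh.Trimesh(kept.vertices, kept.faces, process=True, validate=True)
    loops = _boundary_loops(kept, plane)
    if not loops:
        return trimesh.Trimesh(kept.vertices, kept.faces, process=True, validate=True)
    verts = [kept.vertices]
    faces = [kept.faces]
    base = len(kept.vertices)
    cap_normal = -sign * plane.normal  # caps face away from the kept side
    for loop in loops:
        ring = kept.vertices[loop]
        centroid = ring.mean(axis=0)
        ci = base
        verts.append(centroid[None])
        base += 1
        tri = np.stack([np.full(len(loop), ci), loop, np.roll(loop, -1)], axis=1)
        # orient fan so its normal matches the outward cap normal
        n0 = np.cross(ring[1] - ring[0], centroid - ring[0])
        if np.dot(n0, cap_normal) < 0:
            tri = tri[:, [0, 2, 1]]
        faces.append(tri)
    out = trimesh.Trimesh(np.concatenate(verts), np.concatenate(faces),
                          process=True, validate=True)
    return out
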