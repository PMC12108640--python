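"""Curvature-based ridge extraction on the condylar surface.

Per-vertex principal curvatures are estimated by fitting a quadric height
field over the vertex's one-ring neighbourhood (extended to the two-ring
when the one-ring is too small) in the local tangent frame and
eigen-decomposing the resulting shape operator. High-Gaussian-curvature
feature points are chained into curves by a greedy region-growing rule with
three admission criteria — spatial proximity, curvature consistency and
directional continuity — and finally clipped to the anatomically defined
lateral-condyle box, labelling the posterior retained curve as the capsular
line reference (CLR) and the anterior one as the anterior articular margin.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from ._util import orthonormal_frame, unit
from .volume_mesh import SurfaceMesh


@dataclass
class VertexCurvature:
    """Per-vertex principal curvatures (1/mm) and derived quantities."""

    kappa1: np.ndarray           # larger principal curvature
    kappa2: np.ndarray
    gaussian: np.ndarray         # K = kappa1 * kappa2 (1/mm^2)
    principal_dir: np.ndarray    # (N, 3) unit tangent for kappa1
    valid: np.ndarray            # False where curvature is undefined


@dataclass
class GrowConfig:
    """Admission criteria for the region-growing curve linker.

    ``None`` fields are resolved from the data: eps defaults to 2.5x the
    mean edge length, sigma_k to the interquartile range of K over the
    feature set.
    """

    eps: float | None = None            # spatial proximity (mm)
    sigma_k: float | None = None        # curvature consistency (1/mm^2)
    theta_max: float = 30.0             # directional continuity (deg)
    min_points: int = 3
    max_local_ratio: float = 0.4        # curve-likeness cutoff (see grow_curves)

    def __post_init__(self):
        if not (0.0 < self.theta_max <= 90.0):
            raise ValueError("theta_max must be in (0, 90] degrees")
        for v in (self.eps, self.sigma_k):
            if v is not None and v <= 0:
                raise ValueError("eps and sigma_k must be positive")


@dataclass
class FeatureCurve:
    vertex_ids: np.ndarray
    points: np.ndarray
    label: str = "unlabeled"

    def __len__(self):
        return len(self.points)

    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class AnatomicalRegion:
    """Oriented box: points p with <p - c, e_i> in [l_i, u_i] for all axes."""

    center: np.ndarray
    axes: np.ndarray              # (3, 3), rows e1, e2, e3, orthonormal
    bounds: np.ndarray            # (3, 2), [l_i, u_i] per axis

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        self.bounds = np.asarray(self.bounds, dtype=float)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-8):
            raise ValueError("axes must be orthonormal")
        if np.any(self.bounds[:, 0] >= self.bounds[:, 1]):
            raise ValueError("need l_i < u_i per axis")

    def contains(self, points: np.ndarray) -> np.ndarray:
        q = (np.asarray(points, dtype=float) - self.center) @ self.axes.T
        return np.all((q >= self.bounds[:, 0]) & (q <= self.bounds[:, 1]), axis=1)


def vertex_curvatures(mesh: SurfaceMesh, smooth_iters: int = 0) -> VertexCurvature:
    """Quadric-fit shape-operator curvatures at every vertex.

    Convex surfaces (outward normals) get positive principal curvatures.
    Vertices whose extended neighbourhood stays under 5 points are flagged
    invalid (isolated or boundary-degenerate). ``smooth_iters`` rounds of
    one-ring averaging of the curvatures (with sign-aligned averaging of
    the principal directions) damp the voxel-level noise of
    marching-cubes meshes before thresholding and growth.
    """
    V = mesh.vertices.view(np.ndarray)
    normals = mesh.vertex_normals.view(np.ndarray)
    neighbors = mesh.vertex_neighbors
    n = len(V)
    k1 = np.zeros(n)
    k2 = np.zeros(n)
    dirs = np.zeros((n, 3))
    valid = np.ones(n, dtype=bool)
    for i in range(n):
        nb = list(neighbors[i])
        if len(nb) < 6:
            two = set(nb)
            for j in nb:
                two.update(neighbors[j])
            two.discard(i)
            nb = sorted(two)
        if len(nb) < 5:
            valid[i] = False
            continue
        nrm = normals[i]
        e1, e2 = orthonormal_frame(nrm)
        rel = V[nb] - V[i]
        x = rel @ e1
        y = rel @ e2
        h = rel @ nrm
        # h(x, y) = a x^2 + b xy + c y^2 + d x + e y
        A = np.stack([x * x, x * y, y * y, x, y], axis=1)
        AtA = A.T @ A
        try:
            coef = np.linalg.solve(AtA + 1e-12 * np.eye(5), A.T @ h)
        except np.linalg.LinAlgError:
            valid[i] = False
            continue
        a, b, c, d, e = coef
        w = np.sqrt(1.0 + d * d + e * e)
        I = np.array([[1 + d * d, d * e], [d * e, 1 + e * e]])
        II = -np.array([[2 * a, b], [b, 2 * c]]) / w
        try:
            S = np.linalg.solve(I, II)
        except np.linalg.LinAlgError:
            valid[i] = False
            continue
        evals, evecs = np.linalg.eig((S + S.T) / 2.0)
        evals = np.real(evals)
        order = np.argsort(evals)[::-1]
        k1[i], k2[i] = evals[order]
        u, v = np.real(evecs[:, order[0]])
        dirs[i] = unit(u * e1 + v * e2)
    for _ in range(max(0, smooth_iters)):
        nk1 = k1.copy()
        nk2 = k2.copy()
        nd = dirs.copy()
        for i in range(n):
            nb = [j for j in neighbors[i] if valid[j]]
            if not valid[i] or not nb:
                continue
            ring = nb + [i]
            nk1[i] = np.mean(k1[ring])
            nk2[i] = np.mean(k2[ring])
            signs = np.sign(dirs[ring] @ dirs[i])
            signs[signs == 0] = 1.0
            acc = (dirs[ring] * signs[:, None]).sum(axis=0)
            nrm = np.linalg.norm(acc)
            if nrm > 1e-12:
                nd[i] = acc / nrm
        k1, k2, dirs = nk1, nk2, nd
    K = k1 * k2
    K[~valid] = np.nan
    return VertexCurvature(kappa1=k1, kappa2=k2, gaussian=K,
                           principal_dir=dirs, valid=valid)


def feature_points(
    curv: VertexCurvature,
    tau_K: float | None = None,
    percentile: float | None = 90.0,
) -> np.ndarray:
    """Vertex ids with Gaussian curvature above the threshold.

    Either an absolute ``tau_K`` (1/mm^2) or a ``percentile`` of K over
    valid vertices (default 90) resolves the cutoff.
    """
    K = curv.gaussian
    if tau_K is None:
        if percentile is None:
            raise ValueError("give tau_K or percentile")
        tau_K = float(np.nanpercentile(K, percentile))
    with np.errstate(invalid="ignore"):
        sel = K > tau_K
    sel &= curv.valid
    return np.where(sel)[0]


def _mean_edge_length(mesh: SurfaceMesh) -> float:
    e = mesh.edges_unique
    return float(np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1).mean())


def grow_curves(
    mesh: SurfaceMesh,
    pf: np.ndarray,
    curv: VertexCurvature,
    cfg: GrowConfig | None = None,
) -> list[FeatureCurve]:
    """Chain feature points into ordered curves by greedy region growing.

    Growth starts at the highest-K unused seed and extends both curve ends;
    a candidate joins iff it is within ``eps`` of the frontier point, its K
    differs by at most ``sigma_k``, and its principal direction makes at
    most ``theta_max`` with the frontier point's (directions compared as
    unoriented lines). Candidates are taken nearest-first. Grown clusters
    are ordered into polylines; clusters that are locally two-dimensional
    (median ratio of the second to first local-PCA singular value above
    ``max_local_ratio`` — surface-noise patches rather than ridges) and
    curves shorter than ``min_points`` are dropped. Deterministic for a
    fixed mesh.
    """
    cfg = cfg or GrowConfig()
    pf = np.asarray(pf, dtype=int)
    if len(pf) == 0:
        raise ValueError("empty feature set")
    pts = mesh.vertices.view(np.ndarray)[pf]
    K = curv.gaussian[pf]
    dirs = curv.principal_dir[pf]
    eps = cfg.eps if cfg.eps is not None else 3.5 * _mean_edge_length(mesh)
    if cfg.sigma_k is not None:
        sigma_k = cfg.sigma_k
    else:
        p95, p5 = np.nanpercentile(K, [95, 5])
        sigma_k = max(p95 - p5, 1e-12)
    cos_max = np.cos(np.deg2rad(cfg.theta_max))

    tree = cKDTree(pts)
    used = np.zeros(len(pf), dtype=bool)
    seeds = np.argsort(-K, kind="stable")
    curves: list[FeatureCurve] = []

    for seed in seeds:
        if used[seed]:
            continue
        # breadth-first region growth: a candidate joins via the frontier
        # point that reaches it, under the three admission criteria
        region = [int(seed)]
        used[seed] = True
        frontier = [int(seed)]
        while frontier:
            nxt_frontier = []
            for cur in frontier:
                cand = np.array(tree.query_ball_point(pts[cur], eps), dtype=int)
                cand = cand[~used[cand]]
                if len(cand) == 0:
                    continue
                ok = np.abs(K[cand] - K[cur]) <= sigma_k
                ok &= np.abs(dirs[cand] @ dirs[cur]) >= cos_max
                cand = cand[ok]
                d = np.linalg.norm(pts[cand] - pts[cur], axis=1)
                for j in cand[np.lexsort((cand, d))]:
                    if not used[j]:
                        used[j] = True
                        region.append(int(j))
                        nxt_frontier.append(int(j))
            frontier = nxt_frontier
        if len(region) >= cfg.min_points:
            rpts = pts[np.array(region)]
            if _local_linearity(rpts, 2.0 * eps) > cfg.max_local_ratio:
                continue
            order = _order_region(rpts)
            ids = pf[np.array(region)[order]]
            curves.append(FeatureCurve(vertex_ids=ids,
                                       points=mesh.vertices.view(np.ndarray)[ids].copy()))
    curves.sort(key=lambda c: -c.length())
    return curves


def _local_linearity(p: np.ndarray, radius: float, n_samples: int = 40) -> float:
    """Median second-to-first local-PCA singular-value ratio.

    Close to 0 for points strung along a curve; large (> ~0.5) for points
    spread over a surface patch.
    """
    if len(p) < 6:
        return 0.0
    tree = cKDTree(p)
    sel = np.linspace(0, len(p) - 1, min(n_samples, len(p))).astype(int)
    scores = []
    for i in sel:
        nb = tree.query_ball_point(p[i], radius)
        if len(nb) < 5:
            continue
        q = p[nb] - p[nb].mean(axis=0)
        w = np.linalg.svd(q, compute_uv=False)
        if w[0] > 1e-12:
            scores.append(w[1] / w[0])
    return float(np.median(scores)) if scores else 0.0


def _order_region(p: np.ndarray) -> np.ndarray:
    """Order a grown point cluster into a polyline.

    Starts from the point farthest from the cluster centroid (a curve
    endpoint for elongated clusters) and repeatedly walks to the nearest
    unvisited point. Deterministic.
    """
    n = len(p)
    if n <= 2:
        return np.arange(n)
    start = int(np.argmax(np.linalg.norm(p - p.mean(axis=0), axis=1)))
    tree = cKDTree(p)
    visited = np.zeros(n, dtype=bool)
    order = [start]
    visited[start] = True
    cur = start
    for _ in range(n - 1):
        k = 2
        nxt = None
        while nxt is None and k <= n:
            dd, ii = tree.query(p[cur], k=min(k, n))
            for j in np.atleast_1d(ii):
                if not visited[j]:
                    nxt = int(j)
                    break
            k *= 2
        if nxt is None:
            nxt = int(np.flatnonzero(~visited)[0])
        visited[nxt] = True
        order.append(nxt)
        cur = nxt
    return np.array(order)


def thin_curve(curve: FeatureCurve, curv: VertexCurvature, bin_mm: float = 1.5) -> FeatureCurve:
    """Thin a ridge curve to its crest: keep the maximum-K point per
    arc-length bin of the ordered curve, then re-order the survivors."""
    K = curv.gaussian[curve.vertex_ids]
    pts = curve.points
    if len(pts) < 4:
        return curve
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    nb = max(1, int(np.ceil(s[-1] / bin_mm)))
    edges = np.linspace(0.0, s[-1], nb + 1)
    sel = []
    for i in range(nb):
        m = (s >= edges[i]) & (s <= edges[i + 1])
        if m.any():
            idx = np.flatnonzero(m)
            sel.append(idx[np.argmax(K[idx])])
    sel = np.unique(sel)
    p = pts[sel]
    order = _order_region(p)
    return FeatureCurve(vertex_ids=curve.vertex_ids[sel][order],
                        points=p[order], label=curve.label)


def clip_to_region(
    curves: list[FeatureCurve],
    region: AnatomicalRegion,
    anterior_axis: np.ndarray | None = None,
    min_points: int = 3,
    min_label_frac: float = 0.25,
) -> list[FeatureCurve]:
    """Trim curves to the lateral-condyle box and label the survivors.

    Curves are split where they exit the box; among substantial retained
    segments (length at least ``min_label_frac`` of the longest, so stray
    fragments cannot claim a label) the one with the most posterior
    centroid (along ``anterior_axis``, default the region's second axis) is
    labelled ``CLR`` and the most anterior ``anterior_margin`` (when a
    distinct segment exists).
    """
    ap = np.asarray(anterior_axis, dtype=float) if anterior_axis is not None else region.axes[1]
    segments: list[FeatureCurve] = []
    for c in curves:
        inside = region.contains(c.points)
        if not inside.any():
            continue
        splits = np.flatnonzero(np.diff(inside.astype(int)))
        runs = np.split(np.arange(len(inside)), splits + 1)
        for run in runs:
            if inside[run[0]] and len(run) >= min_points:
                segments.append(FeatureCurve(vertex_ids=c.vertex_ids[run],
                                             points=c.points[run],
                                             label="unlabeled"))
    if not segments:
        warnings.warn("no feature curve intersects the anatomical region")
        return []
    lengths = np.array([s.length() for s in segments])
    cand = np.flatnonzero(lengths >= min_label_frac * lengths.max())
    pos = np.array([segments[i].centroid() @ ap for i in cand])
    segments[int(cand[np.argmin(pos)])].label = "CLR"
    if len(cand) > 1:
        i_ant = int(cand[np.argmax(pos)])
        if segments[i_ant].label == "unlabeled":
            segments[i_ant].label = "anterior_margin"
    return segments


def lateral_condyle_region(
    lateral_mesh: SurfaceMesh,
    axes: np.ndarray | None = None,
    ap_shrink: float = 0.10,
    superior_limit: float | None = None,
) -> AnatomicalRegion:
    """Default lateral-condyle box in the given anatomical frame.

    The box is the mesh bounding box shrunk by ``ap_shrink`` at the
    anterior/posterior faces (extreme-margin artefacts are clinically
    irrelevant). ``superior_limit`` caps the third (superior) axis in world
    units relative to the box centre — callers set it just below the
    intercondylar roof so the shaft is excluded from the condylar region.
    """
    axes = np.asarray(axes, dtype=float) if axes is not None else np.eye(3)
    V = lateral_mesh.vertices.view(np.ndarray)
    if superior_limit is not None:
        sub = V[V @ axes[2] < superior_limit]
        if len(sub) < 10:
            sub = V
    else:
        sub = V
    center = sub.mean(axis=0)
    q = (sub - center) @ axes.T
    lo = q.min(axis=0)
    hi = q.max(axis=0)
    span_y = hi[1] - lo[1]
    lo[1] += ap_shrink * span_y
    hi[1] -= ap_shrink * span_y
    lo[0] += 0.05 * (hi[0] - lo[0])   # keep the resection face out of the box
    if superior_limit is not None:
        hi[2] = min(hi[2], superior_limit - center @ axes[2])
    return AnatomicalRegion(center=center, axes=axes,
                            bounds=np.stack([lo, hi], axis=1))


def curves_to_json(curves: list[FeatureCurve], path: str | Path) -> None:
    payload = [{"label": c.label, "points_mm": c.points.tolist()} for c in curves]
    Path(path).write_text(json.dumps(payload))


def curves_from_json(path: str | Path) -> list[FeatureCurve]:
    data = json.loads(Path(path).read_text())
    return [FeatureCurve(vertex_ids=np.arange(len(d["points_mm"])),
                         points=np.asarray(d["points_mm"], dtype=float),
                         label=d.get("label", "unlabeled"))
            for d in data]
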