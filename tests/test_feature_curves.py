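"""Mesh curvature, ridge growing, anatomical clipping: analytic and
phantom-recovery checks."""
import numpy as np
import pytest
import trimesh
from scipy.spatial import cKDTree

from condylenav import (AnatomicalRegion, FeatureCurve, GrowConfig,
                        clip_to_region, feature_points, grow_curves,
                        lateral_condyle_region, thin_curve, vertex_curvatures)
from condylenav.feature_curves import VertexCurvature


# ---------------------------------------------------------------- curvature

def test_sphere_gaussian_curvature(sphere5):
    cv = vertex_curvatures(sphere5)
    K = cv.gaussian
    assert np.nanmedian(np.abs(K - 0.04) / 0.04) < 0.10
    assert np.median(cv.kappa1) > 0          # convex => positive


def test_plane_curvature_is_zero():
    from scipy.spatial import Delaunay
    xx, yy = np.meshgrid(np.linspace(0, 10, 20), np.linspace(0, 10, 20))
    v = np.stack([xx.ravel(), yy.ravel(), np.zeros(400)], 1)
    mesh = trimesh.Trimesh(v, Delaunay(v[:, :2]).simplices, process=False)
    cv = vertex_curvatures(mesh)
    interior = np.all((v[:, :2] > 1) & (v[:, :2] < 9), axis=1)
    assert np.nanmax(np.abs(cv.gaussian[interior])) < 1e-6


def test_cylinder_principal_curvatures(cylinder_tube):
    cv = vertex_curvatures(cylinder_tube)
    mid = np.abs(cylinder_tube.vertices[:, 2]) < 3
    assert abs(np.median(cv.kappa1[mid]) - 0.5) < 0.02
    assert np.median(np.abs(cv.kappa2[mid])) < 1e-3
    assert np.nanmedian(np.abs(cv.gaussian[mid])) < 1e-3


def test_doubling_scale_halves_curvature(sphere5):
    big = sphere5.copy()
    big.apply_scale(2.0)
    cv1 = vertex_curvatures(sphere5)
    cv2 = vertex_curvatures(big)
    assert abs(np.median(cv2.kappa1) - 0.5 * np.median(cv1.kappa1)) \
        < 0.05 * np.median(cv1.kappa1)
    assert abs(np.nanmedian(cv2.gaussian) - 0.25 * np.nanmedian(cv1.gaussian)) \
        < 0.05 * np.nanmedian(cv1.gaussian)


# ---------------------------------------------------------------- thresholding

def test_feature_points_empty_above_max(sphere5):
    cv = vertex_curvatures(sphere5)
    assert len(feature_points(cv, tau_K=np.nanmax(cv.gaussian) + 1)) == 0


def test_feature_points_match_brute_force(sphere5):
    cv = vertex_curvatures(sphere5)
    tau = float(np.nanmedian(cv.gaussian))
    got = set(feature_points(cv, tau_K=tau))
    expect = {i for i, k in enumerate(cv.gaussian)
              if np.isfinite(k) and k > tau and cv.valid[i]}
    assert got == expect


def test_phantom_crease_vertices_enter_feature_set(phantom_fine, lateral_fine):
    """At the 90th-percentile threshold the planted ridge is well covered."""
    _, _, truth = phantom_fine
    lat, cv = lateral_fine
    pf = feature_points(cv, percentile=90)
    tree = cKDTree(lat.vertices.view(np.ndarray)[pf])
    d, _ = tree.query(truth.crease_polyline)
    assert (d < 1.0).mean() >= 0.80


# ---------------------------------------------------------------- growing

def _fake_mesh(points):
    return trimesh.Trimesh(points, [[0, 1, 2]], process=False)


def _fake_curv(points, direction):
    n = len(points)
    return VertexCurvature(kappa1=np.ones(n), kappa2=np.ones(n),
                           gaussian=np.ones(n),
                           principal_dir=np.tile(direction, (n, 1)),
                           valid=np.ones(n, bool))


def test_single_feature_point_yields_no_curve():
    pts = np.array([[0.0, 0, 0], [100, 0, 0], [200, 0, 0]])
    mesh = _fake_mesh(pts)
    curv = _fake_curv(pts, [0, 1, 0])
    curves = grow_curves(mesh, np.array([0]), curv, GrowConfig(eps=1.0, sigma_k=1.0))
    assert curves == []


def test_two_separated_ridges_give_two_curves():
    line1 = np.stack([np.arange(20) * 0.5, np.zeros(20), np.zeros(20)], 1)
    line2 = line1 + [0.0, 50.0, 0.0]          # 100 x eps away
    pts = np.vstack([line1, line2])
    mesh = _fake_mesh(pts)
    curv = _fake_curv(pts, [0, 0, 1])
    curves = grow_curves(mesh, np.arange(len(pts)), curv,
                         GrowConfig(eps=0.75, sigma_k=1.0))
    assert len(curves) == 2
    assert all(len(c) == 20 for c in curves)


def test_growth_is_deterministic_and_rigid_invariant(phantom_coarse, coarse_mesh):
    from condylenav import Plane, resect_medial
    _, _, truth = phantom_coarse
    lat = resect_medial(coarse_mesh, Plane.from_point_normal([0, 0, 0], [1, 0, 0]),
                        truth.lateral_marker_pt)
    cv = vertex_curvatures(lat, smooth_iters=1)
    pf = feature_points(cv, percentile=92)
    c1 = grow_curves(lat, pf, cv)
    c2 = grow_curves(lat, pf, cv)
    assert len(c1) == len(c2)
    assert all(np.array_equal(a.vertex_ids, b.vertex_ids) for a, b in zip(c1, c2))
    # rigid motion: same vertex chains on the rotated mesh
    T = trimesh.transformations.rotation_matrix(0.5, [1, 1, 0])
    moved = lat.copy()
    moved.apply_transform(T)
    cvm = vertex_curvatures(moved, smooth_iters=1)
    pfm = feature_points(cvm, percentile=92)
    c3 = grow_curves(moved, pfm, cvm)
    ids1 = {tuple(sorted(c.vertex_ids)) for c in c1}
    ids3 = {tuple(sorted(c.vertex_ids)) for c in c3}
    overlap = len(ids1 & ids3) / max(len(ids1), 1)
    assert overlap > 0.8


def test_phantom_crease_recovery(phantom_fine, lateral_fine):
    """The dominant grown curve is the planted capsular ridge: >= 90 %
    arc-length coverage and sub-mm crest distance after thinning."""
    spec, _, truth = phantom_fine
    lat, cv = lateral_fine
    V = lat.vertices.view(np.ndarray)
    pf = feature_points(cv, percentile=90)
    region = lateral_condyle_region(lat, np.eye(3), superior_limit=truth.blumensaat_polyline[:, 2].min() - 1.0)
    pf = pf[region.contains(V[pf])]
    curves = grow_curves(lat, pf, cv)
    longest = thin_curve(curves[0], cv)
    ttree = cKDTree(truth.crease_polyline)
    d, _ = ttree.query(longest.points)
    assert d.mean() < 1.0
    # coverage judged on the part of the planted arc inside the condylar
    # box (the anatomical trim legitimately cuts the extreme margins)
    truth_in = truth.crease_polyline[region.contains(truth.crease_polyline)]
    ctree = cKDTree(longest.points)
    dt, _ = ctree.query(truth_in)
    assert (dt < 1.0).mean() >= 0.90
    assert max(d.max(), dt.max()) < 2.0    # no stray branches


def test_clr_label_lands_on_planted_crease(phantom_fine, lateral_fine):
    _, _, truth = phantom_fine
    lat, cv = lateral_fine
    V = lat.vertices.view(np.ndarray)
    pf = feature_points(cv, percentile=90)
    region = lateral_condyle_region(lat, np.eye(3),
                                    superior_limit=truth.blumensaat_polyline[:, 2].min() - 1.0)
    pf = pf[region.contains(V[pf])]
    curves = grow_curves(lat, pf, cv)
    labeled = clip_to_region(curves, region)
    clr = next(c for c in labeled if c.label == "CLR")
    clr = thin_curve(clr, cv)
    truth_in = truth.crease_polyline[region.contains(truth.crease_polyline)]
    assert np.linalg.norm(clr.centroid() - truth_in.mean(axis=0)) < 3.0


# ---------------------------------------------------------------- clipping

def test_clip_keeps_inside_curve_whole():
    region = AnatomicalRegion(center=np.zeros(3), axes=np.eye(3),
                              bounds=np.array([[-5, 5], [-5, 5], [-5, 5]], float))
    pts = np.stack([np.linspace(-3, 3, 10), np.zeros(10), np.zeros(10)], 1)
    c = FeatureCurve(vertex_ids=np.arange(10), points=pts)
    out = clip_to_region([c], region)
    assert len(out) == 1 and len(out[0]) == 10


def test_clip_split_matches_point_in_box_oracle():
    region = AnatomicalRegion(center=np.zeros(3), axes=np.eye(3),
                              bounds=np.array([[-5, 2], [-5, 5], [-5, 5]], float))
    pts = np.stack([np.linspace(-4, 8, 25), np.zeros(25), np.zeros(25)], 1)
    c = FeatureCurve(vertex_ids=np.arange(25), points=pts)
    out = clip_to_region([c], region)
    inside = region.contains(pts)
    assert len(out) == 1
    assert np.array_equal(out[0].vertex_ids, np.flatnonzero(inside))


def test_clip_outside_warns_and_returns_empty():
    region = AnatomicalRegion(center=np.zeros(3), axes=np.eye(3),
                              bounds=np.array([[-1, 1]] * 3, float))
    pts = np.stack([np.linspace(10, 12, 5), np.zeros(5), np.zeros(5)], 1)
    c = FeatureCurve(vertex_ids=np.arange(5), points=pts)
    with pytest.warns(UserWarning):
        assert clip_to_region([c], region) == []
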