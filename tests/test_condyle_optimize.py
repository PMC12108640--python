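"""Curvature, constrained ellipse fitting, plane optimization, resection."""
import numpy as np
import pytest
import trimesh

from condylenav import (OptimizeConfig, PhantomSpec, Plane, PlanarContour,
                        articular_region, contour_curvature, fit_ellipse,
                        make_mesh_phantom, optimize_cutting_plane,
                        plane_objective, resect_medial, section_series)
from condylenav.sagittal_frame import plane_mesh_contour

FRAME = (np.zeros(3), np.array([1.0, 0, 0]), np.array([0.0, 1, 0]))


def _contour(points, closed=True):
    return PlanarContour(np.asarray(points, float), FRAME, closed=closed)


# ---------------------------------------------------------------- curvature

def test_circle_curvature_is_inverse_radius():
    th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
    c = _contour(np.stack([2 * np.cos(th), 2 * np.sin(th)], 1))
    k = contour_curvature(c)
    assert np.abs(k - 0.5).max() < 1e-3


def test_straight_segment_curvature_is_zero():
    pts = np.stack([np.linspace(0, 10, 50), np.zeros(50)], 1)
    k = contour_curvature(_contour(pts, closed=False))
    assert np.abs(k).max() < 1e-9


def test_ellipse_vertex_curvature():
    th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    c = _contour(np.stack([2 * np.cos(th), np.sin(th)], 1))
    k = contour_curvature(c)
    assert abs(k[0] - 2.0) / 2.0 < 0.01        # a/b^2 at the major vertex


def test_curvature_rejects_stationary_points():
    pts = np.array([[0, 0], [0, 0], [1, 0], [2, 0], [3, 0]], float)
    with pytest.raises(ValueError):
        contour_curvature(_contour(pts, closed=False))


# ---------------------------------------------------------------- ellipse fit

@pytest.mark.parametrize("ab", [(1.0, 1.0), (2.0, 1.0), (3.0, 1.0), (3.0, 2.0)])
@pytest.mark.parametrize("rot_deg", [0.0, 30.0, 60.0])
def test_fit_ellipse_exact_recovery(ab, rot_deg):
    a, b = ab
    t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
    R = np.deg2rad(rot_deg)
    rot = np.array([[np.cos(R), -np.sin(R)], [np.sin(R), np.cos(R)]])
    pts = np.stack([a * np.cos(t), b * np.sin(t)], 1) @ rot.T + [1.5, -0.5]
    fit = fit_ellipse(pts)
    assert np.allclose(fit.semi_axes, (a, b), atol=1e-6)
    assert np.allclose(fit.center, [1.5, -0.5], atol=1e-6)
    e_true = np.sqrt(1 - (b / a) ** 2)
    assert abs(fit.eccentricity - e_true) < 1e-6
    assert fit.residual_rms < 1e-9
    A, B, C = fit.coeffs[:3]
    assert B ** 2 - 4 * A * C < 0


def test_fit_ellipse_needs_six_points():
    t = np.linspace(0, 2 * np.pi, 5, endpoint=False)
    with pytest.raises(ValueError):
        fit_ellipse(np.stack([np.cos(t), np.sin(t)], 1))


def test_fit_ellipse_rejects_collinear():
    pts = np.stack([np.linspace(0, 1, 20), np.linspace(0, 2, 20)], 1)
    with pytest.raises(ValueError):
        fit_ellipse(pts)


# ---------------------------------------------------------------- articular arc

def test_articular_region_keeps_whole_circle():
    th = np.linspace(0, 2 * np.pi, 200, endpoint=False)
    c = _contour(np.stack([np.cos(th), np.sin(th)], 1))
    arc = articular_region(c)
    assert len(arc) == len(c)


def test_articular_region_excludes_straight_weld():
    th = np.linspace(0.25 * np.pi, 1.75 * np.pi, 270)
    arc_pts = np.stack([np.cos(th), np.sin(th)], 1)
    seg = arc_pts[-1] + np.linspace(0, 1, 80)[1:-1, None] * (arc_pts[0] - arc_pts[-1])
    pts = np.vstack([arc_pts, seg])
    c = _contour(pts)
    if c.signed_area() < 0:
        c = _contour(pts[::-1].copy())
    out = articular_region(c)
    r = np.linalg.norm(out.points, axis=1)
    n_straight_kept = int((r < 0.95).sum())
    assert n_straight_kept <= 0.05 * len(seg)


def test_articular_region_contains_major_vertex():
    th = np.linspace(0, 2 * np.pi, 400, endpoint=False)
    c = _contour(np.stack([2 * np.cos(th), np.sin(th)], 1))
    out = articular_region(c)
    d = np.linalg.norm(out.points - np.array([2.0, 0.0]), axis=1)
    d_alt = np.linalg.norm(out.points - np.array([-2.0, 0.0]), axis=1)
    assert min(d.min(), d_alt.min()) < 0.05


# ---------------------------------------------------------------- sections

def test_sphere_section_series_counts(sphere5):
    plane = Plane.from_point_normal([0, 0, 0], [0, 0, 1])
    secs = section_series(sphere5, plane, 3, 1.0, "lateral")
    assert len(secs) == 3
    assert all(s.closed for s in secs)
    # frame origins step by exactly the requested spacing along the normal
    offs = [np.dot(s.frame[0], plane.normal) for s in secs]
    assert np.allclose(np.diff(offs), -1.0, atol=1e-9)


def test_ellipsoid_section_centers_are_collinear():
    mesh, axis = make_mesh_phantom(subdivisions=4)
    plane = Plane.from_point_normal([0, 0, 0], axis)
    secs = section_series(mesh, plane, 5, 2.0, "lateral")
    centers = []
    for s in secs:
        fit = fit_ellipse(s.points)
        centers.append(fit.center)
    centers = np.array(centers)
    # residual of the best-fit 2D line through the section centers
    c = centers - centers.mean(axis=0)
    resid = np.linalg.svd(c, compute_uv=False)[1] / np.sqrt(len(c))
    assert resid < 0.5


def test_two_sphere_objective_is_near_zero():
    spec = PhantomSpec(condyle_radii_medial=(20, 20, 20),
                       condyle_radii_lateral=(20, 20, 20),
                       condyle_separation=60.0)
    mesh, axis = make_mesh_phantom(spec, subdivisions=5)
    plane = Plane.from_point_normal([0, 0, 0], axis)
    med = section_series(mesh, plane, 4, 2.0, "medial")
    lat = section_series(mesh, plane, 4, 2.0, "lateral")
    obj = plane_objective(med, lat)
    assert obj.mean_eccentricity < 0.05
    assert obj.focal_dispersion < 0.5


def test_focal_dispersion_matches_brute_force():
    th = np.linspace(0, 2 * np.pi, 120, endpoint=False)
    circ = np.stack([10 * np.cos(th), 10 * np.sin(th)], 1)
    c1 = _contour(circ)
    c2 = _contour(circ + [5.0, 0.0])
    obj = plane_objective([c1, c2], [c1], use_articular_arc=False)
    # brute-force: foci of each fit, per-side centroids, pooled RMS
    foci = np.concatenate([fit_ellipse(c.points).foci for c in (c1, c2)])
    cen_m = foci.mean(axis=0)
    foci_l = fit_ellipse(c1.points).foci
    cen_l = foci_l.mean(axis=0)
    sq = list(((foci - cen_m) ** 2).sum(axis=1)) + list(((foci_l - cen_l) ** 2).sum(axis=1))
    assert np.isclose(obj.focal_dispersion, np.sqrt(np.mean(sq)), atol=1e-9)


def test_tilted_cylinder_sections_get_more_eccentric():
    def tilted(theta_deg):
        th = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        a = 2.0 / np.cos(np.deg2rad(theta_deg))
        return _contour(np.stack([a * np.cos(th), 2.0 * np.sin(th)], 1))

    o10 = plane_objective([tilted(10)], [tilted(10)], use_articular_arc=False)
    o30 = plane_objective([tilted(30)], [tilted(30)], use_articular_arc=False)
    assert o30.mean_eccentricity > o10.mean_eccentricity


# ---------------------------------------------------------------- optimizer

def test_optimizer_stays_near_optimal_init():
    mesh, axis = make_mesh_phantom(subdivisions=4)
    init = Plane.from_point_normal([0, 0, 0], axis)
    cfg = OptimizeConfig(max_iter=20, use_articular_arc=False)
    plane, _, trace = optimize_cutting_plane(mesh, init, cfg)
    err = np.degrees(np.arccos(min(1.0, abs(float(np.dot(plane.normal, axis))))))
    assert err <= cfg.angle_step_init
    assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))


def test_optimizer_recovers_tilted_axis_within_one_degree():
    mesh, axis = make_mesh_phantom(subdivisions=5)
    tilt = trimesh.transformations.rotation_matrix(np.deg2rad(5), [0, 1, 0])[:3, :3]
    init = Plane.from_point_normal([0, 0, 0], tilt @ axis)
    plane, _, trace = optimize_cutting_plane(mesh, init,
                                             OptimizeConfig(use_articular_arc=False))
    err = np.degrees(np.arccos(min(1.0, abs(float(np.dot(plane.normal, axis))))))
    assert err < 1.0
    assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))


def test_optimizer_equivariant_under_rigid_motion():
    """Rotating mesh + init jointly rotates the result (within the noise
    basin of the discretized objective)."""
    mesh, axis = make_mesh_phantom(subdivisions=5)
    tilt = trimesh.transformations.rotation_matrix(np.deg2rad(4), [0, 0, 1])[:3, :3]
    cfg = OptimizeConfig(use_articular_arc=False)
    p1, o1, _ = optimize_cutting_plane(mesh, Plane.from_point_normal([0, 0, 0], tilt @ axis), cfg)
    T = trimesh.transformations.rotation_matrix(0.6, [1, 0.3, 0.2])
    moved = mesh.copy()
    moved.apply_transform(T)
    init2 = Plane.from_point_normal(T[:3, 3], T[:3, :3] @ (tilt @ axis))
    p2, o2, _ = optimize_cutting_plane(moved, init2, cfg)
    ang = np.degrees(np.arccos(min(1.0, abs(float(np.dot(p2.normal, T[:3, :3] @ p1.normal))))))
    assert ang < 1.0
    assert abs(o1.value - o2.value) < 0.01


# ---------------------------------------------------------------- resection

def test_resect_hemisphere_area(unit_sphere):
    plane = Plane.from_point_normal([0, 0, 0], [0, 0, 1])
    half = resect_medial(unit_sphere, plane, [0, 0, 0.9])
    expect = 2 * np.pi + np.pi          # hemisphere + cap disk
    assert abs(half.area - expect) / expect < 0.05
    assert half.is_watertight


def test_resect_no_intersection_returns_mesh(unit_sphere):
    plane = Plane.from_point_normal([0, 0, -2.0], [0, 0, 1])
    assert resect_medial(unit_sphere, plane, [0, 0, 0]) is unit_sphere


def test_resect_keeps_marker_side(unit_sphere):
    plane = Plane.from_point_normal([0, 0, 0.3], [0, 0, 1])
    kept = resect_medial(unit_sphere, plane, [0, 0, 0.9])
    d = kept.vertices @ plane.normal - plane.offset
    assert d.min() >= -1e-6


def test_resect_marker_on_plane_errors(unit_sphere):
    plane = Plane.from_point_normal([0, 0, 0], [0, 0, 1])
    with pytest.raises(ValueError):
        resect_medial(unit_sphere, plane, [0.5, 0.5, 0.0])
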