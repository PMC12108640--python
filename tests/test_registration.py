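"""Enhancement, edges, SIFT, matching, rigid estimation, ICP, frame
registration."""
import numpy as np
import pytest
import scipy.ndimage as ndi
from scipy.spatial import cKDTree
from skimage.transform import rotate as sk_rotate

from condylenav import (RigidTransform2D, detect_edges, edge_points, enhance,
                        estimate_initial_transform, fit_rigid_2d, icp_refine,
                        match_features, register_frame, render_curve_image,
                        sift_keypoints)
from condylenav.registration import MatchSet


def _entropy(x):
    h, _ = np.histogram(x, bins=64, range=(x.min(), x.max() + 1e-12))
    p = h / h.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------- enhance

def test_enhance_constant_image_unchanged():
    img = np.full((64, 64), 0.3)
    assert np.allclose(enhance(img), img)


def test_enhance_preserves_range_and_raises_entropy():
    rng = np.random.default_rng(0)
    img = ndi.gaussian_filter(rng.random((128, 128)), 4) * 0.1 + 0.4
    out = enhance(img)
    assert out.min() >= img.min() - 1e-9
    assert out.max() <= img.max() + 1e-9
    assert _entropy(out) >= _entropy(img)


def test_enhance_empty_errors():
    with pytest.raises(ValueError):
        enhance(np.empty((0, 0)))


# ---------------------------------------------------------------- edges

def test_edges_constant_image_empty():
    assert detect_edges(np.full((64, 64), 0.5)).sum() == 0


def test_edges_vertical_step_is_thin_connected_line():
    img = np.zeros((64, 64))
    img[:, 32:] = 1.0
    e = detect_edges(img)
    assert e.any()
    cols = np.nonzero(e)[1]
    assert np.ptp(cols) <= 1                  # at most 1 px wide
    assert np.all(e.sum(axis=1) <= 2)
    rows = np.nonzero(e)[0]
    assert len(np.unique(rows)) >= 56          # a connected vertical run


def test_phantom_frame_crease_pixels_near_edges(std_frame):
    """Most projected capsular-line pixels have a Canny edge within 2 px."""
    frame, crease_px = std_frame
    ep = edge_points(detect_edges(enhance(frame)))
    d, _ = cKDTree(ep).query(crease_px)
    assert (d < 2.0).mean() >= 0.80


# ---------------------------------------------------------------- SIFT

def test_sift_blank_image_has_no_keypoints():
    assert sift_keypoints(np.zeros((64, 64))) == []


def test_sift_descriptors_are_128_and_unit_norm():
    rng = np.random.default_rng(1)
    img = ndi.gaussian_filter(rng.random((128, 128)), 2)
    kps = sift_keypoints(img)
    assert len(kps) > 10
    for k in kps[:20]:
        assert k.descriptor.shape == (128,)
        assert np.isclose(np.linalg.norm(k.descriptor), 1.0)


def test_sift_repeatability_under_rotation():
    rng = np.random.default_rng(2)
    img = ndi.gaussian_filter(rng.random((160, 160)), 3)
    rot = sk_rotate(img, 30.0, order=3)
    kp0 = sift_keypoints(img)
    kp1 = sift_keypoints(rot)
    c = (np.array(img.shape[::-1]) - 1) / 2.0
    th = np.deg2rad(-30.0)   # image y points down: ccw on screen = -theta in (x, y)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    p0 = np.stack([k.position for k in kp0])
    expected = (p0 - c) @ R.T + c
    p1 = np.stack([k.position for k in kp1])
    d, _ = cKDTree(p1).query(expected)
    assert (d < 3.0).mean() >= 0.5


# ---------------------------------------------------------------- matching

def test_self_match_has_zero_ratio():
    rng = np.random.default_rng(3)
    D = rng.random((50, 128))
    D /= np.linalg.norm(D, axis=1, keepdims=True)
    ms = match_features(D, D, ratio_thresh=0.75)
    assert len(ms) == 50
    assert all(r < 1e-9 for _, _, r in ms.pairs)
    assert all(i == j for i, j, _ in ms.pairs)


def test_ratio_test_boundary():
    """Nearest 0.6 / second 1.0 accepted; 0.8 / 1.0 rejected at tau=0.75."""
    a = np.zeros((1, 128))
    a[0, 0] = 1.0

    def at_distance(d):
        v = a[0].copy()
        v[1] = d                      # ||v - a|| = d for orthogonal offset
        return v

    b_accept = np.stack([at_distance(0.6), at_distance(1.0)])
    b_reject = np.stack([at_distance(0.8), at_distance(1.0)])
    assert len(match_features(a, b_accept)) == 1
    assert len(match_features(a, b_reject)) == 0


def test_matching_needs_two_candidates():
    a = np.random.default_rng(0).random((3, 128))
    with pytest.raises(ValueError):
        match_features(a, a[:1])


def test_kdtree_matches_equal_brute_force():
    rng = np.random.default_rng(4)
    A = rng.random((200, 128))
    B = rng.random((500, 128))
    ms = match_features(A, B, ratio_thresh=0.95)
    D = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
    brute = []
    for i in range(len(A)):
        order = np.argsort(D[i])
        ratio = D[i, order[0]] / D[i, order[1]]
        if ratio < 0.95:
            brute.append((i, int(order[0])))
    assert [(i, j) for i, j, _ in ms.pairs] == brute


# ---------------------------------------------------------------- rigid fits

def test_procrustes_recovers_exact_transform():
    t = np.linspace(0, 2 * np.pi, 100)
    P = np.stack([10 * np.cos(t), 5 * np.sin(t)], 1)
    T0 = RigidTransform2D.from_angle(np.deg2rad(15), (10, 5))
    F = fit_rigid_2d(P, T0.apply(P))
    assert np.abs(F.R - T0.R).max() < 1e-9
    assert np.abs(F.t - T0.t).max() < 1e-9
    assert F.rmse < 1e-9


def test_initial_transform_identity_case():
    rng = np.random.default_rng(5)
    P = rng.random((30, 2)) * 50
    ms = MatchSet(pairs=[(i, i, 0.1) for i in range(30)])
    F = estimate_initial_transform(ms, P, P)
    assert np.allclose(F.R, np.eye(2), atol=1e-9)
    assert np.allclose(F.t, 0, atol=1e-9)
    assert F.rmse < 1e-12


def test_initial_transform_resists_gross_outliers():
    rng = np.random.default_rng(6)
    P = rng.random((50, 2)) * 100
    T0 = RigidTransform2D.from_angle(np.deg2rad(12), (4, -7))
    Q = T0.apply(P)
    n_out = 10                         # 20 % gross outliers
    Q[:n_out] += rng.uniform(30, 60, size=(n_out, 2))
    ms = MatchSet(pairs=[(i, i, 0.2) for i in range(50)])
    F = estimate_initial_transform(ms, P, Q)
    assert np.degrees(abs(F.angle - T0.angle)) < 1.0


def test_initial_transform_needs_two_matches():
    with pytest.raises(ValueError):
        estimate_initial_transform(MatchSet(pairs=[(0, 0, 0.1)]),
                                   np.zeros((1, 2)), np.zeros((1, 2)))


# ---------------------------------------------------------------- ICP

def test_icp_identity_fixed_point():
    rng = np.random.default_rng(7)
    P = rng.random((80, 2)) * 20
    T = icp_refine(P, P, init=RigidTransform2D.identity())
    assert T.rmse < 1e-12
    assert np.allclose(T.R, np.eye(2), atol=1e-12)


def test_icp_exact_recovery_on_closed_curve():
    t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
    P = np.stack([10 * np.cos(t), 5 * np.sin(t)], 1)
    T0 = RigidTransform2D.from_angle(np.deg2rad(10), (2, 1))
    target = T0.apply(np.vstack([P, P[:1]]))
    init = RigidTransform2D.from_angle(np.deg2rad(-5), (1, 0))
    T = icp_refine(P, target, init=init, tol=1e-12, max_iter=300,
                   target_kind="polyline")
    assert np.abs(T.R - T0.R).max() < 1e-3
    assert np.abs(T.t - T0.t).max() < 1e-3
    assert T.rmse < 1e-6
    assert all(b <= a + 1e-9 for a, b in zip(T.rmse_history, T.rmse_history[1:]))


def test_icp_noisy_crease_rmse_within_tolerance():
    """Short version of the 500-point noisy capsular-line simulation."""
    from condylenav import PhantomSpec
    arc = PhantomSpec().crease_arc
    th = np.deg2rad(np.linspace(*arc.core_span_deg, 500))
    P = np.stack([arc.radius * np.cos(th), arc.radius * np.sin(th)], 1)
    T0 = RigidTransform2D.from_angle(np.deg2rad(10), (1.6, 1.2))
    rmses = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        tgt = T0.apply(P) + rng.normal(0, 0.2, P.shape)
        init = RigidTransform2D.from_angle(np.deg2rad(7), (1.0, 0.7))
        T = icp_refine(P, tgt, init=init, max_iter=200)
        rmses.append(T.rmse)
        assert all(b <= a + 1e-9 for a, b in zip(T.rmse_history, T.rmse_history[1:]))
    assert np.mean(rmses) <= 0.8


def test_icp_degenerate_target_errors():
    P = np.random.default_rng(8).random((10, 2))
    line = np.stack([np.linspace(0, 1, 10), np.zeros(10)], 1)
    with pytest.raises(ValueError):
        icp_refine(P, line)


def test_icp_equivariance_under_target_rotation():
    t = np.linspace(0, 2 * np.pi, 200, endpoint=False)
    P = np.stack([10 * np.cos(t), 5 * np.sin(t)], 1)
    T0 = RigidTransform2D.from_angle(np.deg2rad(8), (1, 2))
    tgt = T0.apply(np.vstack([P, P[:1]]))
    T1 = icp_refine(P, tgt, init=T0, target_kind="polyline", tol=1e-12)
    S = RigidTransform2D.from_angle(np.deg2rad(5), (3, -1))
    tgt2 = S.apply(tgt)
    T2 = icp_refine(P, tgt2, init=S.compose(T0), target_kind="polyline", tol=1e-12)
    expect = S.compose(T1)
    assert np.abs(T2.R - expect.R).max() < 1e-6
    assert np.abs(T2.t - expect.t).max() < 1e-6


# ---------------------------------------------------------------- frames

@pytest.fixture(scope="module")
def notch_view(fine_mesh, phantom_fine):
    from condylenav import CameraModel, render_arthro_frame
    _, _, truth = phantom_fine
    cam = CameraModel.look_at(np.array([-20.0, 0.0, -50.0]),
                              np.array([8.0, -4.0, 2.0]), up=(0, 0, 1),
                              fx=420, fy=420, width=256, height=256)
    frame, crease_px = render_arthro_frame(fine_mesh, cam, truth)
    roof_px, rz = cam.project(truth.blumensaat_polyline)
    ok = (rz > 0) & np.all((roof_px >= 5) & (roof_px < 251), axis=1)
    return frame, [crease_px, roof_px[ok]]


def test_register_phantom_frame_sub_mm(std_frame):
    """Registering a frame against its own projected capsular line leaves
    the curve within 1 mm of its true pixels."""
    frame, crease_px = std_frame
    calib = 0.15
    res = register_frame(frame, [crease_px * calib], calib)
    assert res.status == "ok"
    mapped = res.map_mm(crease_px * calib, calib)
    err_mm = np.linalg.norm(mapped - crease_px, axis=1).mean() * calib
    assert err_mm < 1.0


def test_register_recovers_10px_shift_within_1px(notch_view):
    frame, curves_px = notch_view
    calib = 0.15
    target = render_curve_image([c + np.array([10.0, 0.0]) for c in curves_px],
                                frame.shape)
    res = register_frame(target, [c * calib for c in curves_px], calib,
                         source_mode="edges", icp_max_corr_px=6)
    assert res.status == "ok"
    assert np.abs(res.transform.t - [10.0, 0.0]).max() < 1.0
    assert abs(np.degrees(res.transform.angle)) < 0.5


def test_register_featureless_frame_fails_gracefully():
    res = register_frame(np.full((64, 64), 0.5),
                         [np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 1.0]])], 1.0)
    assert res.status == "failed"
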