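"""Two-stage arthroscopic-to-model registration.

Frames are enhanced with tile-based adaptive histogram equalization and
reduced to edge points with a Canny detector (sigma = 1.2, hysteresis 0.3 /
0.7 of the maximum smoothed gradient magnitude). SIFT keypoints (DoG
detection, 128-dimensional gradient-histogram descriptors) matched under
Lowe's ratio test (tau = 0.75) give an initial rigid alignment between the
frame and a rendering of the projected model curves; iterative closest
point (ICP) between the projected capsular-line points and the frame edge
points refines it. All transforms are planar rigid maps in pixel space;
the mm-per-px calibration converts reported errors to millimetres.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from scipy.spatial import cKDTree
from skimage import exposure, feature

from ._util import rot2d

CANNY_SIGMA = 1.2
CANNY_LOW = 0.3
CANNY_HIGH = 0.7
RATIO_THRESH = 0.75


@dataclass
class ScaleSpaceConfig:
    """SIFT scale-space parameters; k = 2^(1/s) between adjacent scales."""

    n_octaves: int = 4
    intervals_per_octave: int = 3
    base_sigma: float = 1.6
    contrast_thresh: float = 0.01
    edge_thresh: float = 10.0

    def __post_init__(self):
        if self.intervals_per_octave < 1 or self.n_octaves < 1:
            raise ValueError("octaves and intervals must be >= 1")

    @property
    def k(self) -> float:
        return 2.0 ** (1.0 / self.intervals_per_octave)


@dataclass
class Keypoint:
    position: np.ndarray          # (x, y) px
    scale: float
    orientation: float            # rad
    descriptor: np.ndarray        # 128, unit norm


@dataclass
class MatchSet:
    pairs: list[tuple[int, int, float]]   # (index_a, index_b, ratio)
    ratio_thresh: float = RATIO_THRESH

    def __len__(self):
        return len(self.pairs)


@dataclass
class RigidTransform2D:
    R: np.ndarray = field(default_factory=lambda: np.eye(2))
    t: np.ndarray = field(default_factory=lambda: np.zeros(2))
    rmse: float = 0.0
    rmse_history: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        self.t = np.asarray(self.t, dtype=float)

    @classmethod
    def identity(cls) -> "RigidTransform2D":
        return cls()

    @classmethod
    def from_angle(cls, angle_rad: float, t=(0.0, 0.0)) -> "RigidTransform2D":
        return cls(R=rot2d(angle_rad), t=np.asarray(t, dtype=float))

    @property
    def angle(self) -> float:
        return float(np.arctan2(self.R[1, 0], self.R[0, 0]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.R.T + self.t

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """self o other (apply ``other`` first)."""
        return RigidTransform2D(R=self.R @ other.R, t=self.R @ other.t + self.t)

    def inverse(self) -> "RigidTransform2D":
        return RigidTransform2D(R=self.R.T, t=-self.R.T @ self.t)


# ---------------------------------------------------------------------------
# image preprocessing


def enhance(img: np.ndarray, clip_limit: float = 0.01, kernel_frac: float = 0.125) -> np.ndarray:
    """Tile-based adaptive histogram equalization, input range preserved.

    RGB frames are equalized on the luminance (value) channel.
    """
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        return img.copy()
    ks = max(8, int(round(min(img.shape[:2]) * kernel_frac)))
    if img.ndim == 3:
        from skimage.color import rgb2hsv, hsv2rgb
        hsv = rgb2hsv((img - lo) / (hi - lo))
        hsv[..., 2] = exposure.equalize_adapthist(hsv[..., 2], kernel_size=ks,
                                                  clip_limit=clip_limit)
        out = hsv2rgb(hsv)
    else:
        out = exposure.equalize_adapthist((img - lo) / (hi - lo), kernel_size=ks,
                                          clip_limit=clip_limit)
    return out * (hi - lo) + lo


def detect_edges(
    img: np.ndarray,
    sigma: float = CANNY_SIGMA,
    low: float = CANNY_LOW,
    high: float = CANNY_HIGH,
) -> np.ndarray:
    """Canny edge mask; hysteresis thresholds are fractions of the maximum
    Gaussian-smoothed gradient magnitude (so a unit step edge is always
    detected regardless of absolute image scale)."""
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    sm = ndi.gaussian_filter(img, sigma)
    gmag = np.hypot(ndi.sobel(sm, axis=0), ndi.sobel(sm, axis=1))
    gmax = float(gmag.max())
    if gmax < 1e-12:
        return np.zeros(img.shape, dtype=bool)
    return feature.canny(img, sigma=sigma,
                         low_threshold=low * gmax / 4.0,
                         high_threshold=high * gmax / 4.0)


def edge_points(mask: np.ndarray) -> np.ndarray:
    """Edge pixels as (x, y) coordinates."""
    rr, cc = np.nonzero(mask)
    return np.stack([cc, rr], axis=1).astype(float)


# ---------------------------------------------------------------------------
# SIFT keypoints and matching


def sift_keypoints(img: np.ndarray, cfg: ScaleSpaceConfig | None = None) -> list[Keypoint]:
    """DoG keypoints with 128-d descriptors (4x4 spatial bins x 8
    orientations over the 16x16 neighbourhood), unit-normalized."""
    cfg = cfg or ScaleSpaceConfig()
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if min(img.shape) < 32:
        raise ValueError("image must be at least 32x32")
    det = feature.SIFT(n_octaves=cfg.n_octaves, n_scales=cfg.intervals_per_octave,
                       sigma_min=cfg.base_sigma, c_dog=cfg.contrast_thresh,
                       c_edge=cfg.edge_thresh)
    try:
        det.detect_and_extract(img)
    except RuntimeError:
        return []
    kps = []
    for (r, c), s, o, d in zip(det.keypoints, det.sigmas, det.orientations, det.descriptors):
        v = np.asarray(d, dtype=float)
        n = np.linalg.norm(v)
        if n < 1e-12:
            continue
        kps.append(Keypoint(position=np.array([c, r], dtype=float),
                            scale=float(s), orientation=float(o), descriptor=v / n))
    return kps


def match_features(
    a: list[Keypoint] | np.ndarray,
    b: list[Keypoint] | np.ndarray,
    ratio_thresh: float = RATIO_THRESH,
) -> MatchSet:
    """Ratio-test matching via a k-d tree over descriptors.

    For each descriptor in ``a`` the nearest and second-nearest neighbours
    in ``b`` are found; the pair is accepted iff d1/d2 < ratio_thresh.
    Identical to brute-force search.
    """
    da = np.stack([k.descriptor for k in a]) if not isinstance(a, np.ndarray) else np.asarray(a, float)
    db = np.stack([k.descriptor for k in b]) if not isinstance(b, np.ndarray) else np.asarray(b, float)
    if len(da) == 0:
        return MatchSet(pairs=[], ratio_thresh=ratio_thresh)
    if len(db) < 2:
        raise ValueError("need >= 2 candidates for the ratio test")
    tree = cKDTree(db)
    d, idx = tree.query(da, k=2)
    pairs = []
    for i, ((d1, d2), (j1, _)) in enumerate(zip(d, idx)):
        ratio = d1 / d2 if d2 > 1e-15 else (0.0 if d1 < 1e-15 else np.inf)
        if ratio < ratio_thresh:
            pairs.append((i, int(j1), float(ratio)))
    return MatchSet(pairs=pairs, ratio_thresh=ratio_thresh)


# ---------------------------------------------------------------------------
# rigid estimation


def fit_rigid_2d(src: np.ndarray, dst: np.ndarray) -> RigidTransform2D:
    """Closed-form least-squares rigid fit (Procrustes/Kabsch), src -> dst."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if len(src) < 2 or len(src) != len(dst):
        raise ValueError("need >= 2 correspondences")
    ms, md = src.mean(axis=0), dst.mean(axis=0)
    H = (src - ms).T @ (dst - md)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = md - R @ ms
    res = src @ R.T + t - dst
    return RigidTransform2D(R=R, t=t, rmse=float(np.sqrt((res ** 2).sum(axis=1).mean())))


def estimate_initial_transform(
    matches: MatchSet,
    a_pts: np.ndarray,
    b_pts: np.ndarray,
    max_drop_frac: float = 0.5,
    rel_improve: float = 0.05,
) -> RigidTransform2D:
    """Rigid fit over matched positions with greedy residual trimming.

    The worst-residual correspondence is dropped and the fit repeated while
    the RMSE improves by more than ``rel_improve`` relatively, down to at
    most half the matches (ratio-test survivors still contain outliers).
    """
    if len(matches) < 2:
        raise ValueError("need >= 2 accepted matches")
    ia = np.array([p[0] for p in matches.pairs])
    ib = np.array([p[1] for p in matches.pairs])
    P = np.asarray(a_pts, dtype=float)[ia]
    Q = np.asarray(b_pts, dtype=float)[ib]
    keep = np.arange(len(P))
    fit = fit_rigid_2d(P, Q)
    n_min = max(2, int(np.ceil(len(P) * (1.0 - max_drop_frac))))
    while len(keep) > n_min:
        res = np.linalg.norm(P[keep] @ fit.R.T + fit.t - Q[keep], axis=1)
        cand = keep[np.arange(len(keep)) != np.argmax(res)]
        new = fit_rigid_2d(P[cand], Q[cand])
        if fit.rmse - new.rmse <= rel_improve * max(fit.rmse, 1e-12):
            break
        keep, fit = cand, new
    return fit


class _PolylineTarget:
    """Nearest foot point on an ordered target polyline (closed if the
    endpoints coincide)."""

    def __init__(self, pts: np.ndarray):
        self.a = pts[:-1]
        self.b = pts[1:]
        self.ab = self.b - self.a
        self.len2 = np.maximum((self.ab ** 2).sum(axis=1), 1e-300)
        self.mid_tree = cKDTree((self.a + self.b) / 2.0)

    def query(self, q: np.ndarray):
        k = min(8, len(self.a))
        _, seg_idx = self.mid_tree.query(q, k=k)
        seg_idx = np.atleast_2d(seg_idx)
        best_d = np.full(len(q), np.inf)
        best_p = np.zeros_like(q)
        for col in range(seg_idx.shape[1]):
            s = seg_idx[:, col]
            ap = q - self.a[s]
            t = np.clip((ap * self.ab[s]).sum(axis=1) / self.len2[s], 0.0, 1.0)
            foot = self.a[s] + t[:, None] * self.ab[s]
            d = np.linalg.norm(q - foot, axis=1)
            upd = d < best_d
            best_d[upd] = d[upd]
            best_p[upd] = foot[upd]
        return best_d, best_p


def icp_refine(
    source: np.ndarray,
    target: np.ndarray,
    init: RigidTransform2D | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    max_corr_dist: float | None = None,
    target_kind: str = "points",
) -> RigidTransform2D:
    """Planar rigid ICP: T = argmin sum |R x_i + t - y_i|^2.

    Alternates one-way nearest-neighbour correspondence (source -> target)
    with the closed-form rigid update; stops when the RMSE change drops
    below ``tol`` or after ``max_iter``. With ``target_kind='polyline'``
    the target is an ordered curve and correspondences are foot points on
    its segments, which removes the tangential integer-shift minima of
    discrete point sets. The per-iteration RMSE trace is recorded on the
    returned transform and is non-increasing.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if len(src) < 3 or len(tgt) < 3:
        raise ValueError("need >= 3 points in both sets")
    sv = np.linalg.svd(tgt - tgt.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear) target point set")
    if target_kind == "polyline":
        lookup = _PolylineTarget(tgt)

        def correspond(moved):
            return lookup.query(moved)
    elif target_kind == "points":
        tree = cKDTree(tgt)

        def correspond(moved):
            d, j = tree.query(moved)
            return d, tgt[j]
    else:
        raise ValueError("target_kind must be 'points' or 'polyline'")

    T = init or RigidTransform2D.identity()
    T = RigidTransform2D(R=T.R.copy(), t=T.t.copy())
    history: list[float] = []
    for _ in range(max_iter):
        moved = src @ T.R.T + T.t
        d, corr = correspond(moved)
        if max_corr_dist is not None:
            sel = d <= max_corr_dist
            if sel.sum() < 3:
                break
        else:
            sel = np.ones(len(src), dtype=bool)
        rmse = float(np.sqrt((d[sel] ** 2).mean()))
        history.append(rmse)
        T = fit_rigid_2d(src[sel], corr[sel])
        if len(history) >= 2 and abs(history[-2] - history[-1]) < tol:
            break
    moved = src @ T.R.T + T.t
    d, _ = correspond(moved)
    final = float(np.sqrt((d ** 2).mean()))
    history.append(final)
    return RigidTransform2D(R=T.R, t=T.t, rmse=final, rmse_history=history)


# ---------------------------------------------------------------------------
# frame registration


@dataclass
class RegistrationResult:
    transform: RigidTransform2D   # model-projection px -> frame px
    rmse_mm: float
    n_matches: int
    status: str                   # "ok" | "failed"
    diagnostics: dict = field(default_factory=dict)

    def map_mm(self, points_mm: np.ndarray, calib_mm_per_px: float) -> np.ndarray:
        """Map model-projection mm coordinates into frame pixels."""
        return self.transform.apply(np.asarray(points_mm, dtype=float) / calib_mm_per_px)


def render_curve_image(curves_px: list[np.ndarray], shape: tuple[int, int],
                       width: float = 1.5, blur: float = 2.0) -> np.ndarray:
    """Rasterize projected model curves into a grayscale image for SIFT."""
    from skimage.draw import line as draw_line

    img = np.zeros(shape, dtype=float)
    H, W = shape
    for c in curves_px:
        c = np.asarray(c, dtype=float)
        for p, q in zip(c[:-1], c[1:]):
            r0, c0 = int(round(p[1])), int(round(p[0]))
            r1, c1 = int(round(q[1])), int(round(q[0]))
            rr, cc = draw_line(r0, c0, r1, c1)
            ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
            img[rr[ok], cc[ok]] = 1.0
    if width > 1:
        img = ndi.grey_dilation(img, size=int(round(width)))
    if blur > 0:
        img = ndi.gaussian_filter(img, blur)
    return img


def register_frame(
    frame: np.ndarray,
    model_curves_mm: list[np.ndarray],
    calib_mm_per_px: float,
    sift_cfg: ScaleSpaceConfig | None = None,
    ratio_thresh: float = RATIO_THRESH,
    icp_tol: float = 1e-6,
    icp_max_iter: int = 100,
    icp_max_corr_px: float | None = None,
    divergence_factor: float = 5.0,
    source_mode: str = "curves",
) -> RegistrationResult:
    """Full two-stage registration of one frame against the model curves.

    Pipeline: enhance -> Canny edge points; SIFT on (enhanced frame,
    rendered curve image) -> ratio-test matches -> trimmed rigid initial
    transform (identity fallback when matching fails); ICP onto the frame
    edge points. With ``source_mode='curves'`` (default, for shaded frames)
    the ICP source is the projected curve points themselves; with
    ``'edges'`` it is the edge map of the rendered curve image, which
    matches modality when the frame itself is a line rendering. Failure
    (no edges, ICP divergence) is reported in ``status``, not raised.
    """
    curves_px = [np.asarray(c, dtype=float) / calib_mm_per_px for c in model_curves_mm]
    diag: dict = {}
    enh = enhance(frame)
    edges = detect_edges(enh)
    tgt = edge_points(edges)
    diag["n_edge_points"] = len(tgt)
    if source_mode == "edges":
        src = edge_points(detect_edges(render_curve_image(curves_px, frame.shape[:2])))
        if len(src) < 3:
            src = np.concatenate(curves_px, axis=0)
    else:
        src = np.concatenate(curves_px, axis=0)
    if len(tgt) < 3:
        return RegistrationResult(RigidTransform2D.identity(), float("inf"), 0,
                                  "failed", diag | {"reason": "no edges"})

    init = RigidTransform2D.identity()
    n_matches = 0
    try:
        model_img = render_curve_image(curves_px, frame.shape[:2])
        kp_model = sift_keypoints(model_img, sift_cfg)
        kp_frame = sift_keypoints(enh, sift_cfg)
        diag["n_kp_model"] = len(kp_model)
        diag["n_kp_frame"] = len(kp_frame)
        if len(kp_model) >= 2 and len(kp_frame) >= 2:
            ms = match_features(kp_model, kp_frame, ratio_thresh)
            n_matches = len(ms)
            if n_matches >= 2:
                a_pts = np.stack([k.position for k in kp_model])
                b_pts = np.stack([k.position for k in kp_frame])
                cand = estimate_initial_transform(ms, a_pts, b_pts)
                # sanity: reject wild initializations (beyond half a frame)
                if np.linalg.norm(cand.t) < max(frame.shape):
                    init = cand
    except ValueError:
        pass
    diag["n_matches"] = n_matches

    d0, _ = cKDTree(tgt).query(init.apply(src))
    rmse0 = float(np.sqrt((d0 ** 2).mean()))
    try:
        T = icp_refine(src, tgt, init=init, tol=icp_tol, max_iter=icp_max_iter,
                       max_corr_dist=icp_max_corr_px)
    except ValueError as exc:
        return RegistrationResult(init, rmse0 * calib_mm_per_px, n_matches,
                                  "failed", diag | {"reason": str(exc)})
    diag["rmse_init_px"] = rmse0
    diag["rmse_final_px"] = T.rmse
    status = "ok"
    if T.rmse > divergence_factor * max(rmse0, 1e-9):
        status = "failed"
        diag["reason"] = "ICP divergence"
    return RegistrationResult(T, T.rmse * calib_mm_per_px, n_matches, status, diag)
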