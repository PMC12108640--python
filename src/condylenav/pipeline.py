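"""End-to-end pipeline orchestration and configuration.

Stages: reconstruct (segment + refine + marching cubes) -> initial sagittal
plane -> cutting-plane optimization -> medial resection -> feature-curve
extraction (CLR) -> BH grid -> (optionally) frame registration + overlay.
Every stage writes its artifact into the output directory and the manifest
records artifact hashes, the configuration echo and its hash, so reruns
with identical inputs are byte-comparable.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from ._util import unit
from .bh_grid import blumensaat_line, build_grid, lateral_projection
from .condyle_optimize import OptimizeConfig, optimize_cutting_plane, resect_medial
from .feature_curves import (GrowConfig, clip_to_region, curves_to_json,
                             feature_points, grow_curves, lateral_condyle_region,
                             thin_curve, vertex_curvatures)
from .overlay import OverlaySpec, overlay_frame
from .registration import (CANNY_HIGH, CANNY_LOW, CANNY_SIGMA, RATIO_THRESH,
                           ScaleSpaceConfig, register_frame)
from .sagittal_frame import initial_sagittal_plane, load_landmarks
from .volume_mesh import (VolumeImage, extract_surface, refine_mask, save_mesh,
                          segment_volume)


class PipelineError(RuntimeError):
    """Stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    threshold: float | None = 350.0
    morph_radius: int = 1
    surface_smooth_sigma: float = 1.5
    feature_percentile: float = 90.0
    curvature_smooth_iters: int = 2
    calib_mm_per_px: float = 0.15
    canny: tuple[float, float, float] = (CANNY_SIGMA, CANNY_LOW, CANNY_HIGH)
    tau_ratio: float = RATIO_THRESH
    seed: int = 0
    optimize: OptimizeConfig = field(default_factory=OptimizeConfig)
    grow: GrowConfig = field(default_factory=GrowConfig)
    sift: ScaleSpaceConfig = field(default_factory=ScaleSpaceConfig)
    overlay: OverlaySpec = field(default_factory=OverlaySpec)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sub = {"optimize": OptimizeConfig, "grow": GrowConfig,
               "sift": ScaleSpaceConfig, "overlay": OverlaySpec}
        kwargs = {}
        valid = set(cls.__dataclass_fields__)
        for key, val in raw.items():
            if key not in valid:
                raise ValueError(f"unknown config key: {key!r}")
            if key in sub and isinstance(val, dict):
                allowed = set(sub[key].__dataclass_fields__)
                bad = set(val) - allowed
                if bad:
                    raise ValueError(f"unknown {key} config keys: {sorted(bad)}")
                kwargs[key] = sub[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    volume: VolumeImage | str | Path,
    landmarks: dict | str | Path,
    out_dir: str | Path,
    cfg: PipelineConfig | None = None,
    frames: list[np.ndarray] | None = None,
) -> dict:
    """Execute the full preoperative + navigation pipeline.

    ``landmarks`` must provide ``anterior_notch``, ``posterior_notch``,
    ``transverse_normal`` and ``lateral_marker`` (mm); an optional
    ``roof_polyline`` refines Blumensaat's line beyond the two notch
    points. Returns the manifest (also written to manifest.json).
    """
    cfg = cfg or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": cfg.to_dict(),
                      "config_hash": cfg.config_hash(), "stages": []}
    timings: dict[str, float] = {}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, str(exc)) from exc
                return False
        return _Ctx()

    def record(name, **artifacts):
        entry = {"stage": name, "artifacts": {}}
        for key, p in artifacts.items():
            p = Path(p)
            entry["artifacts"][key] = {"file": p.name, "sha256": _sha256(p)}
        manifest["stages"].append(entry)

    # ---- inputs
    with stage("inputs"):
        if not isinstance(volume, VolumeImage):
            volume = VolumeImage.load_nifti(volume)
        if not isinstance(landmarks, dict):
            landmarks = load_landmarks(landmarks)
        for key in ("anterior_notch", "posterior_notch", "transverse_normal",
                    "lateral_marker"):
            if key not in landmarks:
                raise KeyError(f"landmarks missing '{key}'")

    # ---- 1 reconstruct
    with stage("reconstruct"):
        mask = refine_mask(segment_volume(volume, cfg.threshold), cfg.morph_radius)
        mesh = extract_surface(mask, smooth_sigma=cfg.surface_smooth_sigma)
        femur_path = out / "femur.ply"
        save_mesh(mesh, femur_path)
    record("reconstruct", femur=femur_path)

    # ---- 2 initial sagittal plane
    with stage("sagittal_plane"):
        plane0 = initial_sagittal_plane(landmarks["anterior_notch"],
                                        landmarks["posterior_notch"],
                                        landmarks["transverse_normal"],
                                        medial_hint=None)
        # orient the normal toward the lateral marker for a fixed convention
        if plane0.signed_distance(np.asarray(landmarks["lateral_marker"])[None])[0] < 0:
            plane0 = type(plane0)(normal=-plane0.normal, offset=-plane0.offset)
        plane0_path = out / "initial_plane.json"
        plane0_path.write_text(json.dumps({"normal": plane0.normal.tolist(),
                                           "offset": plane0.offset}, indent=1))
    record("sagittal_plane", initial_plane=plane0_path)

    # ---- 3 optimize cutting plane
    with stage("optimize_plane"):
        plane, objective, trace = optimize_cutting_plane(mesh, plane0, cfg.optimize)
        if plane.signed_distance(np.asarray(landmarks["lateral_marker"])[None])[0] < 0:
            plane = type(plane)(normal=-plane.normal, offset=-plane.offset)
        plane_path = out / "plane.json"
        plane_path.write_text(json.dumps({
            "normal": plane.normal.tolist(), "offset": plane.offset,
            "objective": {"mean_eccentricity": objective.mean_eccentricity,
                          "focal_dispersion": objective.focal_dispersion,
                          "value": objective.value},
            "trace": trace}, indent=1))
    record("optimize_plane", plane=plane_path)

    # ---- 4 resect medial condyle
    with stage("resect"):
        lateral = resect_medial(mesh, plane, landmarks["lateral_marker"])
        lateral_path = out / "lateral.ply"
        save_mesh(lateral, lateral_path)
    record("resect", lateral=lateral_path)

    # ---- anatomical frame: x lateral, y anterior, z superior
    ez = unit(np.asarray(landmarks["transverse_normal"], dtype=float))
    ex = unit(plane.normal - np.dot(plane.normal, ez) * ez)
    ey = np.cross(ez, ex)
    axes = np.stack([ex, ey, ez])
    roof_z = float(min(np.dot(landmarks["anterior_notch"], ez),
                       np.dot(landmarks["posterior_notch"], ez)))

    # ---- 5 feature curves
    with stage("features"):
        curv = vertex_curvatures(lateral, smooth_iters=cfg.curvature_smooth_iters)
        pf = feature_points(curv, percentile=cfg.feature_percentile)
        region = lateral_condyle_region(lateral, axes, superior_limit=roof_z - 1.0)
        V = lateral.vertices.view(np.ndarray)
        pf = pf[region.contains(V[pf])]
        if len(pf) == 0:
            raise ValueError("no feature points inside the condylar region")
        curves = grow_curves(lateral, pf, curv, cfg.grow)
        labeled = clip_to_region(curves, region, anterior_axis=ey)
        labeled = [thin_curve(c, curv) if c.label == "CLR" else c for c in labeled]
        clr = next((c for c in labeled if c.label == "CLR"), None)
        if clr is None:
            raise ValueError("no CLR candidate found")
        curves_path = out / "curves.json"
        curves_to_json(labeled, curves_path)
    record("features", curves=curves_path)

    # ---- 6 BH grid
    with stage("grid"):
        proj = lateral_projection(lateral, ex, anterior_hint=ey, superior_hint=ez)
        roof = np.asarray(landmarks.get(
            "roof_polyline",
            np.stack([landmarks["posterior_notch"], landmarks["anterior_notch"]])),
            dtype=float)
        B = blumensaat_line(proj, roof)
        grid = build_grid(proj, B)
        grid_path = out / "grid.json"
        grid.to_json(grid_path)
    record("grid", grid=grid_path)

    # ---- 7 registration + overlay
    if frames is not None and len(frames) > 0:
        import imageio.v3 as iio
        with stage("register_overlay"):
            clr2d = proj.project(clr.points)
            logs = []
            for k, frame in enumerate(frames):
                res = register_frame(frame, [clr2d], cfg.calib_mm_per_px,
                                     sift_cfg=cfg.sift, ratio_thresh=cfg.tau_ratio)
                ov = overlay_frame(frame, grid, res, cfg.calib_mm_per_px,
                                   extra_curves_mm=[clr2d], spec=cfg.overlay)
                fp = out / f"overlay_{k:03d}.png"
                iio.imwrite(fp, (np.clip(ov, 0, 1) * 255).astype(np.uint8))
                logs.append({"frame": k, "rmse_mm": res.rmse_mm,
                             "status": res.status, "n_matches": res.n_matches})
            log_path = out / "registration.jsonl"
            log_path.write_text("\n".join(json.dumps(l) for l in logs))
        record("register_overlay", log=log_path)

    manifest["timings_s"] = timings
    manifest_path = out / "manifest.json"
    hashable = {k: v for k, v in manifest.items() if k != "timings_s"}
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(hashable, sort_keys=True, default=str).encode()).hexdigest()[:16]
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
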