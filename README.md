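# condylenav

Marker-less computer-assisted navigation for anterior cruciate ligament
reconstruction (ACLR), as a tested Python library and CLI. The femoral
tunnel position is the main determinant of ACLR success, and placing it
through a monocular arthroscope is hard: the surgeon has to reconstruct 3D
anatomy from a 2D view. `condylenav` implements the full preoperative +
navigation chain that addresses this without fiducial markers:

1. **3D femoral model processing** — threshold segmentation of CT-like
   volumes, morphological refinement, marching-cubes surface extraction,
   and an initial sagittal plane through the intercondylar-notch landmarks.
2. **Sagittal-profile optimization** — condylar contours are cut by
   parallel planes and fitted with the direct constrained conic fit
   (`Ax² + Bxy + Cy² + Dx + Ey + F = 0`, `B² − 4AC < 0`). When the cutting
   plane is perpendicular to the epicondylar axis, sectional eccentricity
   `e = √(1 − b²/a²)` vanishes and the fitted-ellipse foci coincide; the
   plane orientation is optimized by deterministic coordinate descent on
   `mean(e) + λ · focal_dispersion / scale`, then the medial condyle is
   resected virtually.
3. **Capsular-line extraction** — per-vertex principal curvatures (κ₁, κ₂)
   from a quadric fit over the one-ring, Gaussian curvature `K = κ₁κ₂`
   thresholding (`P_f = {v : K > τ}`), three-criterion region growing
   (proximity ε, curvature consistency σ_k, direction continuity θ_max),
   and anatomical trimming to the lateral-condyle box — yielding the
   capsular line reference (CLR) and anterior margin.
4. **Bernard–Hertel (BH) grid** — in the true lateral view, Blumensaat's
   line B(s) along the intercondylar roof defines the deep–shallow axis
   D(t) (parallel) and height axis H(h) (perpendicular); a 4×4 grid spans
   the lateral condyle and the recommended ACL footprint is placed at
   `t = 24.8 %` from the posterior margin and `h = 28.5 %` from the roof.
5. **Two-stage registration + overlay** — adaptive histogram equalization,
   Canny edges (σ = 1.2, thresholds 0.3/0.7), SIFT keypoints with
   128-d descriptors matched under Lowe's ratio test (τ = 0.75) for the
   initial alignment, planar rigid ICP (`T = argmin Σ|Rxᵢ + t − yᵢ|²`) for
   refinement, and a semi-transparent grid overlay tracked across frames.
6. **Expert concordance** — deviation distances from the grid centre,
   per-group mean ± SD, CV = 100·SD/mean, % within the 2 mm clinical
   threshold, and the three-tier excellent / acceptable / needs-improvement
   classification.

No patient data ship with the package: a first-class **phantom module**
generates synthetic distal femora (two condylar lobes, intercondylar notch,
an oblique roof line, and a planted capsular-line ridge with exact ground
truth) plus rendered arthroscopic-style frames, so every stage is testable
end to end.

## Worked example

```python
import numpy as np
from condylenav import PhantomSpec, make_femur_phantom, PipelineConfig, run_pipeline

spec = PhantomSpec()                       # 0.5 mm voxels, default anatomy
vol, truth = make_femur_phantom(spec)
landmarks = {
    "anterior_notch": truth.notch_anterior_pt,
    "posterior_notch": truth.notch_posterior_pt,
    "transverse_normal": np.array([0.0, 0.0, 1.0]),
    "lateral_marker": truth.lateral_marker_pt,
    "roof_polyline": truth.blumensaat_polyline,
}
manifest = run_pipeline(vol, landmarks, "out/", PipelineConfig())
```

prints/produces (from `out/grid.json`, `out/curves.json`, `out/plane.json`):

```
footprint fractions: [0.248, 0.285]
D, H (mm): 44.0 30.0
CLR points: 48, mean distance to planted crease: 0.56 mm
optimized plane normal vs epicondylar axis: 2.25 deg
```

i.e. the BH grid places the recommended footprint exactly at the published
fractions of the deep–shallow and height axes, the extracted capsular line
sits about half a millimetre from the planted ground-truth ridge (at 0.5 mm
voxel pitch), and the optimized sagittal plane is within a few degrees of
the phantom's true epicondylar axis (sub-degree recovery on analytic,
voxelization-free phantoms — see the test suite).

The same stages are available as subcommands:

```bash
condylenav phantom --seed 7 --out ph/
condylenav run ph/phantom.nii.gz --landmarks ph/landmarks.json --out out/
condylenav evaluate marks.csv --out report.json --cv-only
```

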