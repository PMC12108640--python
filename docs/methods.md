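# Methods

This note documents the models, numerical choices and synthetic-data
design behind `condylenav`, and what the tests do and do not demonstrate.

## The geometric model

The pipeline treats the distal femur as two near-spheroidal condylar lobes
joined to a shaft, separated by the intercondylar notch. Two structural
facts carry the whole method:

* In a **true sagittal section** (perpendicular to the epicondylar axis)
  the articular portion of each condyle is nearly circular. A tilted
  cutting plane turns the sections elliptical and spreads the fitted
  ellipse foci across parallel sections; both effects vanish together at
  the correct orientation. The cutting-plane optimization therefore
  minimizes `mean eccentricity + λ · focal dispersion / scale` over the
  two spherical angles of the plane normal.
* The **capsular line reference (CLR)** — the whitish ridge on the medial
  aspect of the lateral condyle — is a line of high Gaussian curvature on
  the bone surface, and simultaneously a visible curve in the arthroscopic
  view. It serves as the common landmark that ties the 3D model to the
  2D frame.

## Sagittal-profile optimization

* **Sectioning.** `n` parallel planes (default 5 per condyle, 2 mm apart)
  step inward from each condyle's outer extent. The largest closed contour
  per plane is kept. All section frames share in-plane axes, so fitted
  foci are directly comparable across sections ("projected onto a common
  plane").
* **Articular arc.** Real condylar contours include non-articular bone.
  The near-circular articular arc is selected as the minimal-curvature-
  variance sliding window (40 % of arc length) anchored at the curvature
  maximum, extended while the curvature stays within
  `max(3·SD, 0.15·|mean|)` of the window mean. On analytic whole-lobe
  phantoms the full contour *is* the articular profile, so the sub-degree
  recovery tests disable the arc restriction; voxel-phantom runs keep it.
* **Ellipse fit.** Direct constrained least squares (the numerically
  stable split formulation of the 4AC − B² = 1 constraint) on centred,
  scale-normalized coordinates; the conic is un-normalized afterwards.
  Exact to ~1e-9 on noiseless conics.
* **Focal dispersion.** The spread of foci is computed per condyle (RMS
  distance to that condyle's focus centroid) and pooled as an RMS over all
  foci; pooling across condyles would be dominated by the fixed
  medial–lateral separation, which carries no orientation signal.
* **Objective and optimizer.** `mean_ecc + λ·dispersion/scale` with λ = 1
  and `scale` the mean fitted major diameter, minimized by deterministic
  coordinate descent with step halving (initial step 2°, stop when the
  accepted improvement < 1e-4 or the step has halved 6 times). Greedy
  accept-if-improved makes the accepted-objective trace non-increasing by
  construction; there is no randomness anywhere in the optimization.
* **Resolution limits.** On voxelized surfaces the eccentricity of a
  near-circular section has a noise floor `≈ √(2δ/a)` for contour-point
  scatter δ; at 0.5 mm voxels this floor corresponds to roughly 2° of
  tilt. The 1°-recovery property is therefore demonstrated on analytic
  (subdivided-icosphere) phantoms whose chord error is ~3 µm; the voxel
  pipeline is validated at the looser end-to-end level.

## Curvature and ridge extraction

* **Estimator.** Per vertex, a quadric height field
  `h = ax² + bxy + cy² + dx + ey` is fitted over the one-ring (two-ring
  when fewer than 6 neighbours) in the tangent frame; the shape operator
  `S = I⁻¹·II` gives κ₁ ≥ κ₂ and the κ₁ direction. Convex surfaces with
  outward normals get positive curvatures. Optional one-ring averaging
  (2 iterations in the pipeline) damps the voxel-scale noise of
  marching-cubes meshes; principal directions are averaged sign-aligned.
* **Feature set.** `P_f = {v : K > τ}` with τ defaulting to the 90th
  percentile of K.
* **Region growing.** Breadth-first cluster growth from the highest-K
  unused seed; a candidate joins through the frontier point that reaches
  it iff distance ≤ ε (default 3.5× mean edge length), |ΔK| ≤ σ_k
  (default the p95−p5 spread of K over P_f — an interquartile default
  proved narrower than the curvature gradient along a discretized ridge),
  and the unoriented principal-direction angle ≤ θ_max (30°). Clusters
  are ordered into polylines by a deterministic nearest-neighbour walk
  from the point farthest from the centroid.
* **Curve-likeness filter.** A voxelized surface produces patches of
  spurious high-K vertices (grid-aligned "terracing"). Ridges are locally
  one-dimensional: clusters whose median local-PCA singular-value ratio
  (second/first, neighbourhood radius 2ε) exceeds 0.4 are discarded as
  surface patches. Measured values: ~0.18 for the planted ridge band
  versus ≥ 0.47 for noise patches.
* **Crest thinning.** `thin_curve` keeps the maximum-K point per 1.5 mm
  arc-length bin, collapsing the 2–3-vertex-wide ridge band onto its
  crest (~0.5 mm from ground truth at 0.5 mm voxels).
* **Anatomical trimming.** The lateral-condyle box takes its axes from
  the optimized sagittal frame; bounds come from the sub-roof part of the
  lateral mesh, shrunk 10 % antero-posteriorly and 5 % on the medial face
  (keeping the resection cap out). Only segments ≥ 25 % of the longest
  segment's length can claim the CLR / anterior-margin labels; the most
  posterior centroid is the CLR.

## Bernard–Hertel grid

Blumensaat's line is the moving-average-smoothed (window 5) projection of
the intercondylar-roof polyline in the lateral view (orthographic
projection along the epicondylar axis, first frame axis anterior, second
superior). Its first principal component, oriented anteriorly, fixes the
grid orientation; D spans the silhouette extent along it from the
posterior margin, H runs from the roof's median offset to the most
inferior silhouette point. The footprint sits at the published fractions
(24.8 %, 28.5 %) *by construction* — the meaningful tests are therefore
the grid's invariances (scale equivariance, rigid-motion invariance of the
fractions, exact axis orthogonality) and the agreement of the resulting
footprint with an independently computed analytic-silhouette footprint on
the phantom (< 1 mm).

## Registration

* **Preprocessing.** CLAHE on the luminance channel (range preserved);
  Canny with σ = 1.2 and hysteresis thresholds 0.3 / 0.7 *of the maximum
  smoothed gradient magnitude* — absolute thresholds on a [0, 1] image
  would reject even a unit step edge, whose smoothed gradient peaks at
  ~0.33.
* **SIFT stage.** scikit-image's SIFT (4 octaves, 3 intervals per octave,
  128-d descriptors from the 16×16 neighbourhood) on the enhanced frame
  and on a rasterized rendering of the projected model curves; ratio-test
  matching (τ = 0.75) via a k-d tree, identical to brute force; trimmed
  Procrustes for the initial rigid map (drop the worst residual while the
  RMSE improves ≥ 5 %, at most half the matches). When matching fails the
  stage falls back to the identity — two-stage robustness comes from SIFT
  providing the global alignment and ICP the local polish, and neither
  alone suffices: a 10 px displacement already exceeds the pure-ICP basin
  on a smooth arc.
* **ICP.** Planar rigid point-to-point ICP with one-way source→target
  correspondences and the closed-form Procrustes update; RMSE trace
  recorded and non-increasing. An optional point-to-polyline mode matches
  against foot points on an ordered target curve, removing the integer-
  shift tangential minima of discrete correspondences (machine-precision
  recovery on exact data). An optional correspondence cutoff
  (`max_corr_dist`) suppresses far distractor edges.
* **Dimensionality.** Registration is 2D rigid between the frame and the
  lateral-view projection of the model curves, with a global mm-per-px
  calibration supplied explicitly; a monocular arthroscopic frame does not
  constrain a 3D rigid map, and all reported RMSEs are converted to mm
  through the calibration.
* **Tracking.** Frame k is registered by ICP seeded with frame k−1's
  transform; a residual above 2× the running median of accepted RMSEs (or
  a failure) triggers full SIFT re-initialization.

## Concordance

Deviation distances are Euclidean norms in grid-centred coordinates;
groups are summarized by mean, sample SD (n−1), CV = 100·SD/mean and the
percentage within 2 mm, and classified excellent (CV < 15 and > 90 %),
acceptable (15 ≤ CV ≤ 20 and 80 ≤ % ≤ 90, boundaries inclusive — the
published wording is open at the boundaries, so they are assigned to the
middle tier) or needs-improvement. Because the published seven-group
validation reports only mean ± SD per group, a CV-only mode classifies on
the CV cuts alone; applied to the published summaries it reproduces the
42.9 % / 28.6 % / 28.6 % partition. Raw marking coordinates are not
public, so per-group within-2 mm percentages are exercised only on
synthetic marking tables.

## The synthetic phantom

The phantom is built from smooth-blended quasi-signed-distance fields:
two ellipsoidal lobes (default medial 16×24×24 mm, lateral 15×22×22 mm
semi-axes, 46 mm centre separation — adult-scale condyles), an elliptic
shaft stub above an oblique roof plane (slope 0.15, the Blumensaat
analogue), with 2.5 mm fillets at the welds so no spurious sharp ridge
competes with the planted landmark. Default lobes have equal y/z semi-axes
so perfect perpendicular sections are exact circles — the premise of the
plane optimization holds by construction. Intensities follow a two-level
model (bone 700, background 0, threshold 350) with Gaussian noise
(SD 30); identical (spec, seed) pairs are bit-identical.

The CLR is planted as a **raised bead** (torus segment, radius 1 mm,
tapered ends) along a circular arc lying exactly on the lateral lobe:
its crest is the unique convex high-K line and both bead-lobe junctions
are concave, hence invisible to the `K > τ` rule. Subtractive designs
(carved grooves) were rejected because any carve boundary contributes a
second convex rim within a few millimetres of the arc. The ground-truth
crease polyline is the bead crest (arc offset by the bead radius along the
lobe normal), restricted to the untapered core.

Rendered frames use a pinhole camera (origin top-left, x right, y down),
vertex-splat z-buffering, headlight Lambertian shading (|n·v|²) and an
albedo highlight (+100 % within 0.5 mm of the crease) that emulates the
whitish capsular tissue — in real arthroscopy the "white line" is an
albedo contrast, not a geometric one. The projected crease returned with
each frame is the exact pinhole projection of the truth polyline,
visibility-culled against the z-buffer.

**What the phantom does not emulate:** soft tissue, cartilage, fluid and
debris, specularities, lens distortion, anatomical shape variation beyond
ellipsoid parameters, and CT artefacts beyond additive Gaussian noise.
Passing tests demonstrate the geometric and algorithmic correctness of
each stage under known ground truth — not clinical performance on patient
data.

## Problem sizes and determinism

Default phantoms are ~170×110×120 voxels at 0.5 mm pitch (~70 k surface
vertices after resection); analytic recovery properties use
subdivision-5 icospheres (~20 k vertices); ICP benchmarks use 500-point
curves over 20 seeds. Every stochastic component takes an explicit seed;
the optimizer, growth, ordering and rasterization are fully deterministic,
and the pipeline manifest hash is reproducible across reruns.

## Known limitations

* The 2D-rigid reading of frame registration ignores perspective and
  scale error; it is accurate for distant, roughly lateral viewpoints.
* Ridge extraction assumes the mesh resolves the ridge (bead radius ≥ 2
  voxels); heavier mask smoothing trades terracing noise against ridge
  sharpness (pipeline default sigma 1.5 voxels).
* A single-arc landmark leaves a tangential sliding ambiguity in ICP;
  registration should always be given at least two non-concentric curves
  (e.g. CLR plus the roof line) or rely on the SIFT initialization.
* `articular_region` anchors at the global curvature maximum, which is
  appropriate for condyle-like contours with one prominent arc.
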