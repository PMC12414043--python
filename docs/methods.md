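# Methods

`aneuwall` reimplements, as a tested pipeline on synthetic data, an analysis
that links intraoperatively visible thin-walled regions (TWRs) of
intracranial aneurysms — the red, translucent patches a surgeon sees on the
dome — to the local haemodynamic environment computed on the wall surface.
This note records the models, the generator that stands in for patient data,
the numerical choices, and the known limitations.

## The analysis chain

1. **Thin-region identification.** Intraoperative RGB photographs are
   converted to CIELAB (sRGB, D65 illuminant assumed). The operator selects
   a reference region inside a red area; every pixel's colour distance
   (Delta E) to the mean reference colour is computed and thresholded at a
   fixed value of 10. CIE76 (Euclidean distance in Lab) is the default
   formula because it is what the common histogram-based tools compute;
   CIEDE2000 is selectable. The threshold comparison is inclusive
   (`Delta E <= 10`), reading the threshold as an acceptable colour
   deviation. Against intraoperative maps whose Delta E range reaches ~80,
   the threshold corresponds to about 12.5 % of the maximum colour
   difference, and the segmentation reports this fraction. Contrast
   enhancement is a per-channel linear percentile stretch (default 1st–99th)
   computed from and applied to the ROI only: simple, deterministic and
   idempotent at identity settings.

2. **Haemodynamic metrics.** From a per-node tangential wall-shear-stress
   vector series WSS(s, t) over one cardiac cycle [0, T] (and pressure
   p(s, t)), the pipeline computes, per mesh node:

   - TaWSS = (1/T) ∫ |WSS| dt (Pa), trapezoidal quadrature on the stored
     grid;
   - OSI = ½ (1 − |∫ WSS dt| / ∫ |WSS| dt), in [0, 0.5], with the 0/0 case
     (vanishing field) defined as 0;
   - RRT = 1 / (TaWSS (1 − 2 OSI)) (Pa⁻¹); nodes with |denominator| ≤ 1e-9
     are flagged undefined (NaN), never clipped;
   - WSSD = ∂WSSx/∂x + ∂WSSy/∂y + ∂WSSz/∂z (Pa/mm), the divergence of a
     chosen WSS vector field — time-averaged by default, systolic-instant
     as an option (the single-scalar summary convention is not fixed by the
     source analysis, so both are provided);
   - "WSS" as a scalar is the |WSS| at the systolic instant, defined as the
     time index maximising the mesh-mean |WSS|;
   - pressure at systole (default) or time-averaged.

   The spatial gradient in WSSD is a weighted least-squares linear fit over
   each node's 1-ring neighbourhood in ambient 3D coordinates with
   inverse-edge-length weights. It is exact on linear fields and invariant
   under rigid rotations. **Known limitation:** on a curved surface the fit
   carries an O(1) curvature bias for non-linear fields — the
   normal-derivative column of the design (scale d²/2R for spacing d,
   curvature radius R) is nearly collinear with the mean tangential Hessian
   contribution (also d²), so the bias (≈ −(R/2) Σₐ nₐ tr_T Hₐ) does not
   vanish under mesh refinement. The test suite pins the exact linear-field
   behaviour and checks that the quadratic-field error stays bounded across
   resolutions; claims of higher-order convergence would be wrong for this
   estimator.

3. **Regional sampling.** Image masks are projected back to mesh nodes
   through the acquisition camera (front-facing, z-buffer-visible nodes
   whose pixel lies in the mask), or labels are taken directly from
   generator ground truth. Parent-vessel nodes are always excluded: colour
   matches on the parent artery are anatomical false positives. Per
   patient, 2 thin and 2 normal centre points are placed inside label sets
   eroded by a 0.5 mm geodesic margin, choosing the subset that maximises
   pairwise geodesic separation (deterministic, ties to lowest node index);
   candidates are additionally restricted to nodes whose k-nearest patch is
   entirely inside the label, because the erosion margin alone does not
   bound the Euclidean patch radius. Each centre contributes its k = 10
   Euclidean-nearest nodes (centre included; ties to lowest index), giving
   40 rows per patient — 640 rows, 320 thin / 320 normal, for a 16-patient
   cohort. Patches may overlap and are deliberately not deduplicated.

4. **Mixed-effects comparison.** For each metric Y the working model is

   Y_ij = β0 + β1·thin_ij + u_patient(i) + u_region(i,j) + ε_ij,

   REML-fitted (statsmodels MixedLM; random intercept per patient plus a
   variance component for region-within-patient). β1 is the thin-minus-
   normal fixed effect (reference level: normal); CIs and p-values are
   Wald-based, matching the symmetric 95 % intervals usually reported. A
   crossed alternative (random intercepts for patient and for region type)
   is available as "model1" for AIC comparison. AIC is 2k − 2·logLik with
   k counting fixed effects, variance parameters and the residual variance
   (statsmodels does not define AIC for this model class). Optimisation
   tries L-BFGS, Powell and CG in order; non-convergence raises, and
   boundary/singular fits are flagged rather than hidden. A table whose
   fixed effects fit perfectly (zero residual) cannot be profiled by any
   iterative REML fitter; that case returns the exact least-squares
   coefficients with zero variances, flagged singular, with AIC evaluated
   at a machine-precision variance floor.

   Metrics enter the model raw, log-transformed, or normalised by the
   patient-specific signed maximum taken over the **whole** vascular model
   (parent vessel included). OSI, already bounded and scale-free, is always
   analysed raw. WSSD, which can be negative, is divided by the signed
   maximum (the alternative, the maximum absolute value, is a one-line
   change; the signed convention preserves the sign pattern of the
   normalised intercepts).

## The synthetic cohort generator

No patient data are distributed, so a seeded generator supplies surrogates
with the statistical structure the analysis assumes. Per patient:

- **Geometry.** An idealised sidewall aneurysm: a spherical dome
  (radius ~2.5 mm, varied ±10 % per patient) opening into a cylindrical
  parent-vessel stub (radius ~1.2 mm), triangulated at ~1 800 nodes
  (~0.25 mm spacing) with seeded in-surface jitter so triangulations are
  irregular like body-fitted CFD meshes. Coordinates are in mm.
- **Shear field.** One shared positive two-harmonic pulse
  w(t) = 8 + 4 sin(2πt/T) + 1.5 sin(4πt/T + 0.8) Pa over T = 1 s at 64
  time steps (a transient CFD run would use thousands of steps per cycle;
  the desk-scale default keeps the suite fast and both T and the step count
  are configurable). The spatial profile is ~1 on the dome with a
  high-shear band on the parent vessel (factor 7), which realistically
  places the patient-specific maximum used for normalisation outside the
  dome. The primary direction is azimuthal (tangential projection of a
  fixed axis); an optional oscillatory cross-component with node-random
  phase and amplitude (zero cycle integral) makes OSI strictly positive but
  identically distributed in thin and normal wall — by construction there
  is **no** injected OSI effect, matching the null finding this pipeline is
  meant to be able to reproduce.
- **Thin patches.** Two geodesic caps (radius 1.0 mm) on the upper dome.
  Inside a cap the shear magnitude is multiplied by 1.3, pressure by 1.015,
  and a radially expanding tangential component of (wssd_mult − 1) Pa/mm
  (default multiplier 6) is added so the divergence of the time-averaged
  field has a known positive sign in the cap. The divergence amplitude is
  deliberately large enough to dominate the estimator's curvature bias
  (±2.5 Pa/mm, see above); with it, the normalised thin-minus-normal WSSD
  difference sits around +0.03.
- **Nested randomness.** Lognormal intercepts per patient (sd 0.10) and per
  cap (sd 0.08), plus node-level lognormal noise (sd 0.12), mirror the
  patient / region-within-patient / residual decomposition of the mixed
  model. All randomness flows from one integer seed through documented
  per-patient `SeedSequence` spawn keys, so any patient is regenerable in
  isolation.
- **Pressure.** Baseline 80 mmHg (10 665.76 Pa) with a 5 % pulsatile
  component following the waveform and a mild spatial gradient, so
  normalised pressures sit near 0.9–1.0 as in arterial models.
- **Images.** A pinhole camera centred on the thin patch and a z-buffered
  nearest-vertex rasteriser paint thin wall from a red CIELAB cluster,
  other wall pinkish-purple, background dark, plus seeded Gaussian RGB
  noise (sd 3/255 by default). Nearest-vertex colouring makes the
  image↔mesh correspondence exact, so with zero noise the Delta E mask at
  threshold 10 equals the ground truth pixel-for-pixel and back-projection
  recovers the thin node set exactly.

### What the generator does not emulate

Navier–Stokes flow physics (the fields are constructed, not solved), vessel
wall compliance, realistic photographic effects (glare, specularity, depth
of field), brain shift or registration error (the camera transform is known
exactly), and spatially correlated measurement noise. Passing tests
therefore demonstrate that the pipeline recovers known effects injected
under the model's own assumptions — not that those assumptions hold for
real intraoperative data.

## Calibration companion

`simulate_lmm_table` draws sample tables directly from the nested
two-level model (default: 16 patients × 4 regions × 10 nodes, β1 = 0.03,
patient sd 0.02, region sd 0.05, residual sd 0.07). It is used for the
bias / CI-coverage / type-I studies (200–400 replicates) where re-running
the full field pipeline would be wasteful; the full pipeline's own effect
recovery and direction pattern are checked separately on complete cohorts.

## Numerical choices

- Quadrature: trapezoidal on the stored time grid; with two cycles
  supplied, only the second would be integrated (steady-state convention).
- RRT guard: ε = 1e-9 in Pa; undefined nodes propagate as NaN.
- Patch distance is Euclidean (nearest CFD nodes around a coordinate);
  erosion distance is geodesic (along-wall margins are what "away from the
  boundary" means on a folded surface).
- Centre selection is algorithmic (max geodesic separation) rather than
  manual so the pipeline is reproducible; real-data use can supply explicit
  centre coordinates instead.
- Mixed-model CIs are Wald (normal quantiles). With 16 patients the
  empirical type-I rate of the β1 test is ~4–6 % and CI coverage ~92–94 %,
  measured by the acceptance script.
- Degenerate inputs (self-intersecting ROI polygons, empty reference
  regions, log of non-positive values, zero patient maxima, too-small
  eroded regions, cameras that miss the mesh) raise explicit errors naming
  the offending object.

## Known limitations

- The WSSD estimator's curvature bias (above) means absolute WSSD values on
  curved wall carry an O(R⁻¹|W|) systematic component; thin-vs-normal
  contrasts remain meaningful because the injected divergence dominates.
- The synthetic colour clusters are well separated (ΔE ≈ 44); real
  intraoperative imagery with glare or blood film will be harder, and the
  Dice ≥ 0.95 figure should not be read as an expected clinical accuracy.
- Lognormal multiplicative random effects in the field generator are not
  exactly the additive Gaussian structure of the fitted model; the
  calibration companion, which is exactly additive, is the basis for the
  coverage/type-I claims.
- Only middle-cerebral-artery-like idealised geometry is generated; no
  bifurcations, no patient-specific lumen shapes.
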