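# Methods

This note records the models, conventions and numerical choices behind
`tapse3d`, in the order the pipeline applies them.

## Measurement model

**Inputs.** One ordered 3D contour of the tricuspid annulus per cardiac
reconstruction phase (coordinates in mm; typically 10 phases at 10 %
R–R increments), with four labeled landmark vertices (septal, lateral,
anterior, posterior) and an RV volume (ml) per phase. Landmark
correspondence across phases is the data supplier's responsibility —
the package performs no anatomical landmark detection, and contours are
consumed as segmented (no voxel data).

**Phase selection.** End-systole is the phase of minimum RV volume,
end-diastole the maximum; ties break toward the earliest phase
fraction. A flat volume curve is an error, since no systole can be
identified.

**Directional TAPSE.** For each landmark, the default measure is the
full 3D Euclidean displacement between its ED and ES positions. This is
the minimal reading of "distance between the systolic and diastolic
positions" and is invariant under rigid motion of the whole heart in
the scanner frame. A `long_axis` mode (projection of the displacement
onto the ED best-fit-plane normal) is provided for sensitivity
analysis, since annular excursion is sometimes reported as a long-axis
distance; the default is documented, not configurable per call site.

**TAPSE volume.** Each contour gets its own total-least-squares plane
(SVD of the centred points; the plane passes through the vertex
centroid). Contours are projected onto their own planes and the
shoelace formula gives areas A₁ (ED) and A₂ (ES) — the A₁/A₂ naming is
immaterial under the symmetric mean. The displacement D is the absolute
orthogonal distance from the **ES contour centroid to the ED best-fit
plane**. The reverse convention differs only when the two planes are
not parallel; a `symmetric` option averages both distances. The volume
is D·(A₁+A₂)/2 in mm³, divided by 1000 (one constant, one place) to
report ml.

**"Centre of mass".** The annulus centroid is the unweighted mean of
the contour vertices. Segmented contours are near-uniformly sampled
closed curves, so vertex averaging and arc-length weighting agree to
well below measurement noise; the choice is isolated in one function
(`geometry.centroid`) should an area- or arc-length-weighted variant
ever be needed.

**BSA indexing.** Du Bois: BSA = 0.007184 · weight^0.425 ·
height^0.725 (kg, cm → m²), the default of the echocardiography
community. Plausibility bounds (height 100–250 cm, weight 25–300 kg)
reject unit mix-ups such as metres for centimetres. Directional TAPSE
and TAPSE volume are divided by BSA (mm/m², ml/m²).

## Geometry kernel conventions

* Plane normals are unit vectors with a fixed sign: non-negative z
  component, ties broken toward +y then +x. Distances are absolute
  values, so the convention never leaks into results.
* Polygon area is computed in a deterministic in-plane basis (first
  axis: in-plane projection of the global axis least aligned with the
  normal), making the value independent of basis, cyclic reindexing and
  traversal direction.
* Simplicity is verified by O(n²) pairwise segment intersection after
  projection — contours carry at most a few hundred vertices, so a
  sweep line would be needless machinery.
* Tolerances: unit-norm 1e-12; coplanarity for area evaluation 1e-8 mm;
  consecutive-duplicate vertices 1e-9 mm. All sit far below the 0.5 mm
  CT slice thickness, so they can only trip on genuinely degenerate
  input. Collinear point sets are rejected (the fitted plane would not
  be unique) with the offending contour named in the error.

## Outcome analysis

Records carry time-to-first-event (days), an event flag (death or
heart-failure rehospitalization), and named covariates.

* **Kaplan–Meier**: product-limit estimator with right censoring
  (via `lifelines`); the 1-year endpoint rate is read from the curve as
  1 − S(365 d) rather than as a raw proportion, and median follow-up is
  the reverse-KM median.
* **Log-rank**: standard two-group test, p from χ²₁.
* **Cox**: partial-likelihood proportional-hazards fits with **Efron**
  tie handling — day-resolution follow-up produces heavy ties, where
  Efron is markedly less biased than Breslow. Wald CIs and p-values.
  Complete-case handling per model with logged exclusion counts; zero
  events, perfectly collinear covariates and non-convergence are
  errors, not warnings.
* **Screen → multivariate**: every candidate is fit univariately;
  those with p < 0.1 are retained; the default multivariate stage fits
  one pairwise model per retained CT metric together with the LVEF
  anchor. This mirrors the common small-cohort design in which
  collinear CT metrics are never placed in a single saturated model
  (a saturated model over all retained covariates is what you get when
  the anchor itself fails the screen, or via an explicit `model_spec`).
* **ROC cutoff**: candidate thresholds are midpoints between
  consecutive sorted unique values; AUC is the trapezoid over the full
  (FPR, TPR) staircase; the orientation (high- or low-positive) is
  chosen to give AUC ≥ 0.5. The optimal cutoff maximises Youden's
  J = sens + spec − 1, with ties broken toward higher specificity and
  then toward the lowest threshold. The scan is implemented directly
  (not via a library ROC) because the grid and tie-break are part of
  the package contract; a Mann–Whitney AUC and an exhaustive
  brute-force scan serve as independent cross-checks in the tests.
  No multiple-testing correction is applied anywhere; the significance
  and screen thresholds (0.05, 0.1) live in the config.
* **Subgrouping**: three groups from RVEF ≥ 45 % and posterior iTAPSE
  > 4.5 mm/m² (both preserved / exactly one / both reduced). The
  boundary conventions are deliberately asymmetric — RVEF exactly at
  the cut counts preserved, iTAPSE exactly at the cut counts reduced —
  matching how the thresholds are conventionally written (≥ 45 %,
  > 4.5 mm/m²).

## Synthetic data

The motion generator builds an ED ellipse (defaults 22 × 20 mm
semi-axes, i.e. ≈ 43 mm mean annulus diameter, 64 vertices) and, per
phase, (i) scales the in-plane ring so the enclosed area falls by
`area_pulsation_fraction` (default 15 %) at peak systole, and (ii)
displaces each vertex along the annulus normal by a smooth ring profile
that interpolates the four landmark excursions with a cosine falloff —
this keeps the ring a simple closed curve while letting the four
landmarks move by exactly their configured amounts. Default excursions
are 15/15/13/12 mm (septal/lateral/anterior/posterior), cohort-scale
values for severe tricuspid regurgitation. The temporal waveform is a
C¹-periodic squared sine peaking at 40 % R–R; the RV volume curve
(default 180→110 ml) takes its minimum at the same phase, so phase
selection and motion are mutually consistent. Measurement noise is
isotropic Gaussian per vertex (default σ 0.5 mm, the CT slice
thickness) smoothed circularly over ≈ 3 vertices: segmentation error is
spatially coherent, and uncorrelated per-vertex noise of that magnitude
would create self-crossing rings no segmentation would produce. Setting
`noise_correlation_vertices=0` restores independent noise. Ground truth
is the measurement of the noise-free contours; with zero area pulsation
each directional truth equals the configured excursion exactly.

The cohort generator draws biometrics and covariates from cohort-scale
normal distributions (posterior iTAPSE 6.5 ± 2.4 mm/m², iTAPSE volume
7.4 ± 3.1 ml/m², RVEF 50 ± 10 %, LVEF 54 ± 9 %, TTE TAPSE 19 ± 6 mm,
clipped to plausible ranges) and samples event times from an
exponential proportional-hazards model — the simplest generator exactly
consistent with the Cox model being tested. The effect is either a
binary group (default: posterior iTAPSE > 4.5 mm/m², group HR 0.225,
baseline 2.8 · 10⁻³ events/day, chosen so the reduced group reaches a
1-year event rate near 64 %) or continuous per-unit. Censoring is an
administrative horizon (default 730 d) plus uniform dropout for a
configurable fraction of patients. The full study bundle writes 75
contour files plus a clinical CSV, with each patient's hazard driven by
their *true* noise-free posterior iTAPSE (continuous effect, HR 0.775
per mm/m²), so the simulated endpoint genuinely depends on the quantity
the pipeline later measures through noise.

**What the generators do not emulate** — and hence what passing tests
cannot show about real data: true annular saddle shape and its phase
dynamics (the simulated ring is a displaced ellipse), regional wall
tethering, atrial-fibrillation beat-to-beat variability, correlation
between body size and excursion, non-proportional or time-varying
hazards, and informative censoring. Recovery results certify the
*estimators*, not the clinical effect sizes.

## Problem sizes and tolerances in the validation suite

Geometry identities are checked to 1e-9 relative (closed-form polygons,
cylinder volume) against independent oracles: a 2° exhaustive
normal-grid search for the plane fit, fan triangulation for areas,
direct minimisation for distances. Ground-truth motion recovery uses
1e-6 (noise-free) and a 0.2 mm bias bound on the posterior excursion
mean over 100 noisy seeds. Hazard recovery runs 200 replicates of
n = 500 cohorts (geometric-mean HR within ±10 %, CI coverage within
90–98 %, and the same under the null); the log-rank null is compared to
χ²₁ over 2,000 label permutations (Kolmogorov distance < 0.05); the
end-to-end run is verified byte-identical across reruns at n = 75.
These sizes keep the full suite around a minute while leaving all
Monte-Carlo bounds several standard errors wide.

## Known limitations

* The proportional-hazards fits carry no formal proportionality
  diagnostics; violations surface only through lifelines' warnings.
* The ROC cutoff is a point estimate; no confidence interval or
  cross-validated cutoff is provided.
* Directional TAPSE conflates longitudinal excursion with in-plane
  annular translation under the default Euclidean mode; use
  `long_axis` mode to isolate the normal component.
* `rv_volume` and RVEF are inputs, not computed: the package measures
  the annulus, not the chamber.
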