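# tapse3d

CT-based 3D morphometry of the tricuspid annulus, and the outcome
analysis that goes with it.

Tricuspid annular plane systolic excursion (TAPSE) is the standard
bedside surrogate of longitudinal right-ventricular function, but the
single M-mode distance measured on echocardiography samples only the
lateral corner of a complex, saddle-shaped annulus and has performed
poorly for risk stratification before transcatheter tricuspid valve
intervention (TTVI). Full-cycle cardiac CT with AI segmentation yields
the entire 3D annulus contour at every reconstruction phase, from which
richer excursion measures can be computed. `tapse3d` implements those
measures and the downstream statistics for researchers working with
segmented annulus contours and clinical follow-up tables.

## What it computes

Given per-phase annulus contours (ordered 3D point rings with four
labeled landmarks) and an RV-volume-per-phase curve:

* **Phase selection** — end-systole (ES) and end-diastole (ED) are the
  phases with minimum and maximum RV volume.
* **Directional TAPSE** — the 3D displacement (mm) of the septal,
  lateral, anterior and posterior annular landmarks between ED and ES.
* **TAPSE volume** — the volume of the slab swept by the annulus:
  fit a least-squares plane to each contour, project each contour onto
  its own plane, take the shoelace areas A₁ (ED) and A₂ (ES) and the
  orthogonal distance *D* from the ES annulus centroid to the ED plane,
  then

  &nbsp;&nbsp;&nbsp;&nbsp;V = D · (A₁ + A₂) / 2&nbsp;&nbsp;&nbsp;(reported in ml).

* **BSA indexing** — all measures divided by Du Bois body surface area
  (iTAPSE, mm/m²; iTAPSE volume, ml/m²).
* **Outcome analysis** — ROC with Youden-index optimal cutoffs,
  Kaplan–Meier curves with log-rank tests and group hazard ratios at
  configurable dichotomizations (defaults: posterior iTAPSE 4.5 mm/m²,
  iTAPSE volume 9 ml/m²), a univariate Cox screen (p < 0.1) feeding
  pairwise multivariate models anchored on LVEF, and a three-group
  RVEF × posterior-iTAPSE stratification (RVEF ≥ 45 % preserved).

Because patient CT data of this kind are not publicly deposited, the
package ships first-class synthetic generators: a dynamic elliptical
annulus with configurable landmark excursions, systolic area reduction
and spatially correlated segmentation noise, and a survival-cohort
simulator with an exponential proportional-hazards event model — both
pure functions of (config, seed), returning their ground truth so every
pipeline stage is testable end to end.

## Worked example

```python
from tapse3d import (MotionSimConfig, simulate_annulus_sequence,
                     measure_sequence, Biometrics, index_measurements)

cfg = MotionSimConfig(noise_sd=0.0, area_pulsation_fraction=0.0)
seq, truth = simulate_annulus_sequence(cfg)
result = measure_sequence(seq)
for k, v in result.as_dict().items():
    print(f"{k:>16s}  {v:.3f}")
```

```
        es_phase  0.400
        ed_phase  0.000
    tapse_septal  15.000
   tapse_lateral  15.000
  tapse_anterior  13.000
 tapse_posterior  12.000
         area_a1  1380.081
         area_a2  1380.392
  displacement_d  13.750
    tapse_volume  18.978
```

The simulator was configured with landmark excursions of 15/15/13/12 mm
(septal/lateral/anterior/posterior) and no noise, and the pipeline
recovers them exactly. The ED annulus is a 64-gon ellipse with
semi-axes 22 × 20 mm, whose polygon area is 1380.08 mm²; the annulus
centroid travels 13.75 mm (the mean of the interpolated ring excursion),
giving a TAPSE volume of 13.75 · (1380.08 + 1380.39)/2 / 1000 ≈ 18.98 ml.
Indexing to a patient of 170 cm / 73.35 kg (Du Bois BSA 1.846 m²):

```python
indexed = index_measurements(result, Biometrics(170.0, 73.35))
print(f"{indexed.itapse_posterior:.2f} mm/m²")   # 6.50
print(f"{indexed.itapse_volume:.2f} ml/m²")      # 10.28
```

A posterior iTAPSE of 6.50 mm/m² is above the 4.5 mm/m² risk cutoff, so
this synthetic patient would fall in the preserved-excursion group.

## Command line

```sh
tapse3d simulate --out study/ --n-patients 75 --seed 1
tapse3d measure  --contours study/contours --clinical study/clinical.csv \
                 --out study/measurements.csv
tapse3d analyze  --measurements study/measurements.csv \
                 --clinical study/clinical.csv \
                 --cutoffs posterior_itapse=4.5,itapse_volume=9 \
                 --out study/results
tapse3d run-all  --out study/ --seed 1   # chains all three
```

`analyze` writes `measurements.csv`, `cutoffs.json`, `km_curves.csv`,
`km_summary.json`, `cox_models.json`, `subgroups.csv` and a
`run_log.json` (config, seed, versions, input hashes, exclusions) that
suffices to reproduce the run; reruns with the same seed are
byte-identical.

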