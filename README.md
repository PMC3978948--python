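# bmlpipe

Semi-automated volumetry of knee bone marrow lesions (BMLs) and the
longitudinal cohort analyses that relate BML volume to knee pain and
radiographic joint space narrowing (JSN).

BMLs are ill-defined hyperintense regions in subchondral bone on
fat-suppressed knee MRI. Their volume is a candidate imaging biomarker for
osteoarthritis trials: a useful surrogate would have to track both symptoms
(WOMAC pain) and structure (JSN progression). `bmlpipe` implements the full
computational chain needed to study that question on simulated data:

1. **Phantom simulation** — anisotropic knee-MR-like volumes
   (0.357 x 0.511 mm in-plane, 3 mm slices) with super-ellipsoid femur and
   tibia, bright ellipsoidal lesions of known volume, and reader-style
   boundary annotations, all with exact voxel-level ground truth.
2. **Segmentation** — per-slice edge-attracted active-contour refinement of
   the annotated bone boundaries, then a thresholding (interior
   mean + k·SD) + two-phase piecewise-constant curve-evolution pass run
   twice (the second pass re-estimates the interior statistics with the
   first pass's detections removed).
3. **Quantification** — the operational BML definition: delete the central
   nine slices, require a span of at least two slices and a nearest
   approach to the articular surface of at most 10 mm; assign each lesion
   to medial/lateral femur/tibia; report per-region, total-knee and
   index-compartment volumes in cm³ and their 24-month change.
4. **Cohort analysis** — baseline-volume tertiles; volume-change
   collapsed-quartile classes (regression / minimal / progression);
   three OLS pain models; robust (M-estimation) pain-change models within
   tertiles; three logistic JSN models with Wald CIs and c-statistics;
   quartile linearity checks with covariate dichotomisation (age >= 65 y,
   BMI >= 30 kg/m²); CART (Gini splits, rpart-style risk pruning); a
   medial-compartment sensitivity analysis; and a proportional-odds model
   of cartilage-thickness-loss tertiles on fixed ±3.2 cm³ change classes,
   guarded by a score test of the proportional-odds assumption.
5. **Synthetic cohorts** — generators that reproduce the study-scale
   marginals (n = 404, 49% female, age 62.9 ± 9.2 y, baseline total BML
   volume 2.6 ± 2.7 cm³ clamped to 0.1–15.5 cm³) and inject known effects
   (pain slopes 0.16 and 0.21 points/cm³; per-cm³ JSN odds ratios 1.50 and
   1.28; a 0.95 cm³ CART risk step; ordinal class ORs 2.72/2.06), so every
   estimator is validated by parameter recovery.

## Worked example

Run the whole pipeline (one phantom knee pair plus a 60-knee cohort) from
the shell:

```sh
bmlpipe run --seed 0 --out demo_run
```

The manifest reports the imaging recovery for the demo phantom, which
carries a 1.0 cm³ lateral-tibia and a 0.5 cm³ medial-femur lesion, the
former shrunk by 0.5 cm³ at follow-up:

```
"measured_total_baseline_cm3": 1.4957,
"true_total_baseline_cm3":     1.5001,
"measured_change_cm3":        -0.5101,
"true_change_cm3":            -0.5002
```

i.e. the segmentation recovers the total lesion burden to 0.3% and the
longitudinal change to 2%, despite 1 mm annotation jitter and image noise.

From Python, the JSN side looks like this:

```python
from bmlpipe.cohort import CohortSpec, generate_cohort
from bmlpipe.analysis import fit_jsn_models

table = generate_cohort(CohortSpec(n=375, seed=1))
m1 = fit_jsn_models(table)["baseline_jsn"]
print(m1.table.round(3))
```

```
                estimate     se  pvalue  odds_ratio  ci_low  ci_high
const             -0.624  0.250   0.013       0.536   0.328    0.875
bml_index_base     0.479  0.094   0.000       1.614   1.343    1.940
female            -0.275  0.225   0.220       0.759   0.489    1.179
age_ge65           0.395  0.238   0.097       1.484   0.931    2.365
bmi_ge30           0.550  0.227   0.015       1.734   1.112    2.703
```

The `bml_index_base` row is the per-cm³ odds ratio of baseline JSN for
index-compartment BML volume, adjusted for sex and the dichotomised age and
BMI (here 1.61 on a single draw whose injected truth is 1.50; the
c-statistic for this fit is 0.70). Averaged over many seeds the fitted OR
converges to the injected value — that recovery is what the test suite
asserts.

Individual stages are also exposed as `bmlpipe simulate`, `segment`,
`quantify`, `analyze` and `report`; volumes travel as NIfTI, annotations as
JSON, cohorts as CSV (with a column dictionary written alongside).

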