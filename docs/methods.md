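# Methods

This note documents the models implemented in `bmlpipe`, the design of the
synthetic-data generators, the numerical choices, and what the passing
tests do and do not establish.

## Imaging chain

### Phantoms

A phantom is a `128 x 128 x 24` voxel grid at `0.357 x 0.511 x 3.0` mm
spacing (the sagittal fat-suppressed knee protocol this pipeline targets).
Femur and tibia are super-ellipsoids (exponent 3) separated by a 2 mm
joint gap; the articular surface of each bone is the set of boundary
voxels exposed toward the joint line. The slice axis plays the
medial/lateral role; the grid midline is the split coordinate, and the
medial side takes ties. Bones are deliberately not anatomically realistic:
the segmentation algorithms only require closed boundaries with an
articular sheet.

Lesions are ellipsoids rasterised by **exact voxel count**: the target
volume is converted to a voxel count and the count nearest voxels (in the
ellipsoid metric) are taken, so every ground-truth volume is correct to
one voxel (0.000547 cm³) and follow-up deltas are exact by construction.
Lesion intensity sits `contrast_sd` noise-SDs above the bone interior
(raw units when the phantom is noiseless). Background/soft tissue is
brighter than bone interior (70 vs 40 by default), giving the boundary
contrast the refinement stage locks onto. All generators are pure
functions of spec + seed.

Annotations emulate a reader marking the bone outline per slice: points
are resampled uniformly along the true contour, displaced by at most the
requested jitter, and flagged articular/non-articular by which side of the
bone centre they fall on (the non-articular points stand for the far
cutoff at the epiphyseal line).

### Bone refinement

Per slice, the annotation polygon is resampled to a dense closed contour
and iterated (8 iterations by default): each vertex moves a fraction
(0.4) of the way toward the strongest gradient-magnitude response within
±1.5 mm along its local normal, followed by a circular moving-average
smoothing (window 5). The final polygon is rasterised and filled. On
noiseless phantoms with exact annotations this yields Dice ≈ 0.997
against the true bone; with 1 mm jitter and 10% noise it stays ≥ 0.95.
A slice with fewer than three points, or whose contour rasterises to
fewer than three voxels, raises an error naming the bone and slice.
Later bones yield to earlier ones on overlap, keeping femur and tibia
disjoint.

### Hyperintensity detection

Within each bone the interior mean and SD are estimated and voxels above
`mean + k·SD` (default `k = 1.5`) seed a two-phase piecewise-constant
(Chan–Vese type) morphological curve evolution (20 iterations). The
procedure runs twice: the second pass re-estimates the interior statistics
with the first pass's detections excluded and the two results are
unioned. The original method's threshold rule and curve-evolution details
are not published, so both are configuration here; the "twice" is read as
re-estimation of background statistics after removing first-pass
detections.

Two evolution details matter numerically:

* curves evolve **slice-wise in 2-D**. The slice spacing (3 mm) is an
  order of magnitude coarser than the pixel spacing, so isotropic 3-D
  morphological smoothing erodes a lesion's end slices; in-plane curves
  do not.
* the morphological smoothing strength is 2. At strength 1 the evolution
  keeps noise clusters (volume overestimated ~30%); at 2–3 the lesion
  boundary is stable and the recovered volume is within 2% of truth at
  4 SD contrast.

The candidate mask is always intersected with the bone mask. A constant
interior returns an empty mask, not an error. Raising `k` can only shrink
the seed (monotonicity), and `k <= 0` is rejected.

### Candidate extraction and the BML definition

Connected components use 26-connectivity; distances to the articular
surface are Euclidean under the anisotropic spacing (distance transform of
the articular voxel set). The lesion-definition filter then (1) deletes
voxels in the central excluded block — for `S` slices and an excluded
count of 9 the block starts at `(S - 9) // 2`, sitting one slice toward
index 0 when `S` is even; (2) recomputes span and distance on the
surviving voxels; (3) keeps candidates with distance ≤ 10 mm (inclusive,
measured at the nearest voxel, not the centroid) and span ≥ 2 slices.
The filter is contractive and idempotent. Region assignment requires the
candidate to lie in exactly one bone; the centroid side of the split
decides medial vs lateral, ties medial. Volumes are voxel count times
voxel volume, reported in cm³; the total is the sum of the four regions,
and the index-compartment volume is femur + tibia on the side with the
greater baseline JSN grade (ties medial).

## Cohort generator

One row per knee, two visits 24 months apart. Demographics are drawn from
the study-scale marginals (age 62.9 ± 9.2 y, 49% female, weight
85.0 ± 15.4 kg, height 1.70 ± 0.10 m; BMI derived). Defaults are the
conditions all recovery tests run under.

**Baseline total BML volume** is lognormal clamped to 0.1–15.5 cm³, with
the pre-clamp parameters solved (from the closed-form clipped-lognormal
moments) so the clamped draw has mean 2.6 and SD 2.7 exactly.

**Volume change** is multiplicative with baseline-dependent drift:
`V_fu = V·exp(g)`, `g ~ N(-0.033 - 0.127·ln V, 0.5)`. The three constants
were calibrated once against the printed change structure: overall change
mean ≈ −0.2 cm³, collapsed-quartile cuts near −0.8 and +0.4 cm³, and the
tertile pattern in which small-baseline knees cluster in the minimal
class (≈ 80%) with essentially no regressors while most large-baseline
knees regress (≈ 55%). The realised change SD is ≈ 1.8 cm³, somewhat
below the printed 2.1 — the joint targets are not all attainable in this
family and the quartile/tertile structure was prioritised because the
downstream classifications depend on it.

**Compartments.** A knee prefers the medial side with probability 0.85;
the medial volume share is Beta(7,3) (medial-dominant) or Beta(3,7), held
fixed across visits. For a knee that ends up with no JSN the grade tie
rule makes its index compartment medial, so the sides of no-JSN
lateral-preference knees are relabelled (side labels are exchangeable at
grade 0/0); without this the presence model's predictor would differ from
the volume that generated the outcome and the fitted OR is biased upward
by ~10%.

**JSN.** Baseline presence follows a logistic model in index-compartment
volume with the injected per-cm³ OR (default 1.50); the intercept is
solved at generation time so the sample prevalence matches 246/375.
Present knees get an index grade from (0.58, 0.32, 0.10) over grades
1–3; the other side never exceeds it. Grade-3 knees are not at risk.
Progression among at-risk knees is again logistic in baseline index
volume (OR 1.28 per cm³, rate solved to 68/350), optionally replaced by a
step-risk function (used to plant a CART split) or augmented with
medial-change-class effects (used for the sensitivity-analysis contrast).
Progression is realised as a grade increase (70%) or a within-grade flag
(30%).

**WOMAC pain** must live on the bounded 0–20 support while carrying exact
injected slopes. Each knee has a latent propensity
`u ~ Beta(kappa·m/20, kappa·(1 - m/20))` with `m = b0 + 0.16·V` points,
and both visits draw binomial scores from it: the baseline is
`Binomial(20, u)` and the follow-up `Binomial(20, min(u·f, 1))` with
`f = 1 + shift/m`, `shift = 0.21·ΔV` (or a tertile-specific slope).
Because the multiplicative factor preserves the conditional mean, the
expected pain change equals the injected shift wherever
`m + shift > 0` — which holds across the study's volume range — rather
than being attenuated ~15% as it is under hard clamping of a latent
normal. The cost is a pain-change SD of ≈ 2.2 (printed: 3.0) and a
right-skewed, zero-inflated change distribution (≈ 29% exact zeros,
close to the printed 25%).

**Confirmatory cohort.** BML change is `N(0.9, 4.9)`, chosen so the fixed
±3.2 cm³ thresholds reproduce the 21/49/33-of-103 class mix. The
cartilage outcome is generated through the latent-logistic representation
of the proportional-odds model (class shifts `ln 2.72` and `ln 2.06` plus
standard logistic noise, scaled to mm), so any tertile cut of the outcome
satisfies proportional odds exactly with the injected ORs — which is what
makes both the effect-recovery and the score-test type-I experiments
well-posed.

## Statistical models

Pain models are OLS (`womac_base` or `pain_change` on total volume or its
change, plus sex, weight, height, age); rank-deficient designs raise an
error naming the collinear columns; missing data are complete-case per
model with counts logged. JSN models are maximum-likelihood logistic fits
with Wald CIs on the log-odds scale, a ROC c-statistic, and (for the
change-class model) a 2-df Wald overall p; quasi-separation falls back to
IRLS with a pseudoinverse and flags `unstable_ci` when any SE exceeds 10.
Stratification uses empirical tertile/quartile cut points with ties to
the lower group; the change classes collapse the middle quartiles into
the reference. Age and BMI are dichotomised at 65 y and 30 kg/m², the
boundary mapping upward. The quartile linearity check refits the model
with quartile indicators and reports the four point estimates plus a
monotonicity verdict.

**Robust tertile models.** The within-tertile pain-change fits use
M-estimation. The default norm is Huber with tuning constant `t = 2.0`
and Huber's proposal-2 scale rather than the conventional bisquare/MAD
pair: pain-change scores are discrete with a large point mass at zero, so
the MAD collapses and hard-rejection norms discard the legitimate tail of
the distribution, attenuating a planted slope by ~25%. The wide Huber
norm keeps protection against gross outliers (verified against OLS under
10% contamination) at near-OLS efficiency on clean data; `bisquare` and
the classical 95%-efficiency Huber remain selectable.

**CART.** Splits maximise the Gini decrease over all midpoints of every
numeric predictor (an O(n²) exhaustive search, cross-checked against both
a brute-force oracle and scikit-learn's tree); growth respects
`min_split = 20`, `min_leaf = 7`, `max_depth = 10`; the grown tree is
pruned bottom-up on the misclassification-risk scale with complexity
penalty `cp = 0.01` relative to the root risk, i.e. rpart's convention.
At these defaults the implementation reproduces R `rpart`'s per-seed
split counts on null data almost exactly — including the fact that both
keep occasional spurious splits; a binding penalty (`cp = 0.05`)
collapses null trees to the root leaf in every seed tested.

**Proportional odds.** The confirmation model is a cumulative-logit fit
(`statsmodels` `OrderedModel`) of cartilage-loss tertiles on the fixed
±3.2 cm³ change classes. The assumption check is a score test of equal
slopes across thresholds: the analytic score of the
threshold-specific-slopes model is evaluated at the constrained MLE, the
observed information is obtained by central differences of that score,
and `U'I⁻¹U` is referred to chi² with `p·(J-2)` df. When the test rejects
at 0.05 the coefficient table is withheld (the model "is not reported"),
with the test statistic still exposed in the diagnostics. Under exactly
proportional data the empirical type-I rate over 200 seeds is ~4–8%.

## Problem sizes and budgets

The test suite and the acceptance script choose sizes that make the
Monte-Carlo statements sharp but cheap: phantoms are `128 x 128 x 24`
(one full segmentation ≈ 5 s), recovery experiments use 100–150 seeds at
the study's n (404 pain / 375 presence / 350 progression), the score-test
level uses 200 null seeds, and the demo cohort in the pipeline run is
n = 60. Mean-recovery assertions use a 3.5-SEM tolerance, which leaves
~1 SEM of headroom for the O(1/n) bias of logistic MLEs at these sizes.

## Known limitations

* The phantom emulates geometry and contrast, not MR physics: no bias
  field, no partial-volume averaging, no anatomical shape variation.
  Passing segmentation tests therefore demonstrate algorithmic
  correctness on well-posed inputs, not clinical-grade robustness.
* The cohort generator injects effects only through BML volumes;
  covariates are independent noise, so adjusted and unadjusted estimates
  coincide in expectation and the fitted c-statistics (~0.64–0.65) run
  slightly below values seen with confounded covariates.
* The pain-change SD and the change-volume SD undershoot their printed
  values (2.2 vs 3.0; 1.8 vs 2.1) as the price of exact injected slopes
  and the printed quartile structure, respectively.
* CART cut-point localisation of a planted 0.95 cm³ step is limited by
  the data density near the threshold: the empirical Gini argmax lands
  within ±0.1 cm³ in ~85% of seeds at n = 350, an estimator-variance
  floor (R rpart behaves identically) rather than an implementation
  defect.
* The within-grade JSN progression flag is a generator input, not a
  measurement model of sub-grade scoring.
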