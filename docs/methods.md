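# Methods

This note records the models, conventions and design choices behind
`lge-zmap`, in the order the pipeline runs.

## Geometry: segments, layers, aggregation

**Wall map.**  AHA segments are grouped as anterior {1, 7, 13, 17},
lateral {5, 6, 11, 12, 16}, inferior {4, 10, 15}, septal {2, 3, 8, 9, 14}
— a partition of all 17 segments with five septal segments.

**Circumferential sectors.**  Basal and mid slices use six 60° sectors
counterclockwise from the anterior RV-insertion ray; the ray itself is the
anterior/anteroseptal boundary, so 0–60° is anteroseptal.  Apical slices
use four 90° sectors with the septal sector spanning 45–135°, the standard
45°-rotated apical convention.  The RV-insertion angle is a required
per-slice input, not auto-detected.  Angles follow the mathematical
convention (degrees, counterclockwise from +x); rotating the image content
and the insertion angle together leaves the output table unchanged up to
pixel-sampling tolerance.

**Longitudinal levels.**  Non-apex slices are split into basal/mid/apical
thirds ordered base → apex; indivisible remainders go to the more basal
level (10 slices → 4/3/3).  Slices without a blood pool (no endocardial
contour, or zero endo area) are the apex, segment 17.  Within apex caps,
where two-surface depth is undefined, a pseudo-depth is measured from the
cap centre outward so that segment 17 still receives nine layers.

**Transmural depth and shells.**  Depth at a point is
d_endo / (d_endo + d_epi), the normalized two-sided distance to the
contours — robust to non-convex contours, unlike radial ray casting.
0 is the LV endocardium; 1 is the epicardium, which in the septum is the
RV-side endocardium.  The nine shells are equal-width depth intervals
[(2k−1)/20, (2k+1)/20) centred at 10 %…90 %; pixels with depth outside
[0.05, 0.95) are discarded as partial-volume rim (blood pool, epicardial
fat).  This reconciles "nine equally spaced layers" with the 10–90 %
surface labels.  Contours are closed polygons in mm, vertices
counterclockwise; pixel centres at (j+½)dx, (i+½)dy decide membership
(half-open convention).  Cells that receive no pixels are emitted flagged,
so a patient's table always has 153 rows.

## Tissue characterization

Classes by the ratio r = intensity / max SI: healthy r < 0.40, border
zone 0.40 ≤ r ≤ 0.60 (both boundaries inclusive to BZ, matching the
"40–60 %" convention), core r > 0.60.  The reference max SI is the
patient's maximum over all non-excluded LV units (global-LV scope).
Thresholds are configurable; raising `healthy_max` can only shrink
BZ+core%.  In table mode each segment-layer cell counts as one unit, so a
cell's "percentage" outcome is a 0/100 indicator and regional percentages
are cell means; in image mode units are pixels.  This table/image
divergence is deliberate and documented here: the table carries one mean
per cell, not the pixel histogram.

## Z-score standardization

Per patient, μ and σ pool **all** non-excluded cells across the 17
segments and 9 layers jointly (reading "across all myocardial segments and
layers of the entire LV" as each patient's own LV — cohort-wise pooling
would reintroduce the cross-scanner variability the method exists to
remove).  σ is the sample standard deviation (n − 1); the convention is
configurable via `ddof`.  Constant intensities raise a degenerate-variance
error; fewer than two usable cells an insufficient-data error.  Per
patient, mean(z) = 0 and sd(z) = 1 to 1e−9, and z is invariant to affine
rescaling x → a·x + b (a > 0).  Note the tissue classes are invariant to
pure rescaling (a·x) but not to offsets, since they are ratios of raw
intensities.

## Group comparison

The group contrast is a **linear mixed model**
y = α + β·I(CS) + u_patient + v_layer + ε with crossed (not nested)
random intercepts, fit by REML; β is reported with Wald 95 % CI and
p-value, DCM as reference.  Outcome-unit coefficients with symmetric CIs
are the quantity of interest here (a z or percentage-point difference),
which a logistic link could not produce.  Crossed effects are fit in
statsmodels as two variance components over a single super-group; if that
fit is singular or non-convergent the model falls back to a patient-only
random intercept and finally to OLS, each with a logged warning.  A
constant outcome (e.g. a tissue class absent everywhere) short-circuits to
β = 0, p = 1 rather than a spurious near-zero p-value.  In the balanced
designs the generator produces, the fixed-effect contrast equals the OLS
group-mean difference, which the tests exploit as an oracle.

The battery fits 4 walls × {z, BZ%, core%, BZ+core%} plus 4 walls ×
3 bands for z — 28 tests, raw p-values, no multiplicity correction.  Each
fit reports n_obs, the number of non-excluded cells analysed; with 22
patients and no exclusions these are 990 / 990 / 594 / 792 per wall and
330 / 198 per five- and three-segment band respectively.

**LOWESS profiles.**  Tricube-weighted local **linear** regression of cell
z on layer depth, one curve per group, evaluated on the nine-point grid;
default bandwidth 0.6 (fraction of data in each window).  Local-linear
smoothing reproduces linear trends exactly, which fixes the boundary bias
a local-constant smoother would show at depths 0.1 and 0.9.  The
implementation is cross-checked against statsmodels' classical LOWESS in
the test suite.  Windows whose data are all at one depth return the mean
at that depth.

## Classifier

The patient feature is the **mean z over septal segments × depths
0.7–0.9** (the RV endocardial third; the aggregation over the band's 15
cells is the arithmetic mean).  Decision rule: CS-positive when feature ≥
threshold, the orientation in which CS enhances.  The ROC is a step
function over the unique feature values ∪ {±∞} (ties step simultaneously);
AUC is the trapezoidal integral, equal to the Mann–Whitney concordance.
The operating threshold maximizes Youden's J = sensitivity + specificity
− 1, ties broken toward the higher (more specific) threshold; J ≤ 0
everywhere triggers an inverted-orientation warning.

Cross-validation is stratified k-fold (default k = 5) with a seeded
shuffle: the threshold is fit on the training folds, and the held-out fold
yields the fold AUC and the sensitivity/specificity at that threshold.
The mean ROC averages fold TPRs vertically on a 101-point FPR grid.  The
reported threshold is either the full-data Youden threshold (default) or
the mean of per-fold thresholds (`threshold_mode="per-fold"`); both are
offered because either convention is defensible.  k = n is accepted as a
degenerate leave-one-out check: single-class held-out folds contribute no
fold AUC and the pooled held-out AUC is reported instead.

PPV and NPV follow Bayes' rule from (sensitivity, specificity, prevalence)
and are rounded only at presentation (2 decimals); percentages elsewhere
round half-up to one decimal.

## Synthetic cohorts

The generator emulates the study conditions: a default 13 DCM / 9 CS
cohort at segment-layer granularity.  Cell intensities are baseline noise
(default Gaussian, mean 10, SD 10 arbitrary units — a signed, PSIR-like
scale on which healthy myocardium sits below 40 % of the sample maximum so
all three tissue classes are populated; a Rician option serves
magnitude-image emulation) plus additive lesion offsets:

- **DCM**: a deterministic mid-wall stripe, segments {2, 3} × depths
  {0.4–0.6}, of `effect_size`·SD.
- **CS**: each septal segment lesioned independently with probability
  `cs_patch_rate` (default 0.6); lesion weight grows linearly with depth
  (maximal at 0.9), and each lesioned segment is transmural (full weight
  everywhere) with probability 0.5.  An optional mild anterior trend is
  off by default.

Device artifact is drawn per segment (`artifact_rate`, default 0), flagging
all nine layers, as ICD artifact affects contiguous wall regions.  Every
cohort carries its ground truth (labels, per-cell offsets, implied z-scale
band difference).

**Calibration.**  Standardization attenuates a localized offset: adding
c·σ to m of n cells shifts the patient mean by c·m/n and inflates the SD
by √(1 + c²(m/n)(1−m/n)), so the expected band-mean z difference is
c(1−p)/√(1 + c²p(1−p)), p = m/n = 15/153.  `generate_calibrated_cohort`
inverts this relation numerically so the **z-scale** group difference
equals the requested Δ exactly — the estimand of the recovery experiments
is known by construction (verified empirically: mean β̂ ≈ 0.50 at Δ = 0.5
over 200 replicates).

**Image mode** draws concentric (mildly shrinking toward apex) circular
contours with an analytic intensity field f(angle, depth) plus noise, so
segment-layer means have closed forms: constant fields reproduce the
constant, f = depth reproduces k/10 per shell.

What the generator does **not** emulate: MR physics (inversion recovery,
surface-coil shading), spatially correlated noise, lesion shapes within a
cell, wall-thickness variation, and any calibration of lesion burden to
the real cohort (the study does not quantify per-patient burden).  Passing
tests therefore demonstrate the pipeline's statistical correctness under
its stated assumptions, not clinical performance on real CMR.

## Simulation sizes

Statistical validation uses cohorts larger than the 22-patient default to
stabilize recovery: CI coverage runs 200 replicates of 60 DCM / 40 CS at
Δ = 0.5 (observed coverage ≈ 97 %), the effect-size monotonicity check 25
replicates per Δ ∈ {0, 0.25, 0.5, 1}, and the null calibration 100
permuted-label 13/9 cohorts (mean CV AUC ≈ 0.5).  All seeds derive from a
single user-supplied seed.

## Known limitations

- The crossed-random-effects fit on large regions is the runtime
  bottleneck (~1 s per fit at 100 patients); the fallback hierarchy trades
  exactness of the variance structure for robustness, never silently.
- Table-mode tissue percentages weight cells equally, losing pixel-count
  information available in image mode.
- Apex layering uses a pseudo-depth (no second surface exists at the cap);
  apical-band statistics should be interpreted accordingly.
- The real study's coefficients and AUC depend on its unavailable patient
  data; this package reproduces the arithmetic, the bookkeeping and the
  method's statistical behaviour, not those numbers.
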