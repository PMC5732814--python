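# Methods

This note records the models, conventions and numerical choices behind
`radsurv`, and what the synthetic test bed does and does not establish.

## Feature extraction

**Quantization.** In-mask intensities are mapped to `Ng = 32` grey levels by
equal-width binning of the per-patient in-mask range:
`level = min(floor(Ng·(x−xmin)/(xmax−xmin)) + 1, Ng)`.  This is the standard
reading of "uniform resampling" to a fixed level count; it is monotone in
intensity and invariant to positive affine rescaling, so every texture
feature inherits invariance to linear intensity calibration.  A
constant-intensity ROI maps entirely to level 1 rather than erroring —
degenerate, but it keeps all matrices well defined and all features finite,
which downstream rank statistics and forests require.  Per-patient min–max
bounds (rather than a fixed HU window) were chosen because the emulated data
are single-scanner CT; a fixed window is the natural extension for
multi-scanner work and would change the features' meaning, not the code
path.  Voxel geometry is used as stored — no grid resampling — since the
emulated acquisitions are isotropic; spacing enters only the shape features.

**Texture matrices.** All three matrices are 3D and mask-aware (background
voxels never enter any count):

- *GLCM*: pair counts over the 13 unique direction offsets at Chebyshev
  distance 1, both voxels in-mask, symmetric accumulation, counts merged
  across offsets before normalizing.  Merging gives a single
  direction-agnostic matrix per ROI and makes features invariant under axis
  permutation.
- *NGTDM*: for each in-mask voxel with at least one in-mask 26-neighbor,
  the absolute difference from the neighborhood mean (center excluded,
  in-mask neighbors only) accumulates into its level's `s_i`.  Voxels with
  no in-mask neighbor are skipped.
- *GLZM*: zones are maximal 26-connected components of equal-level voxels;
  26-connectivity is the most permissive 3D choice and the usual one for
  zone matrices.

Degenerate-input conventions: GLCM correlation is defined as 0 when a
marginal variance vanishes; NGTDM coarseness is capped at `1/ε = 1e12`
(constant ROI); busyness, contrast and strength fall back to 0 when their
denominators vanish.  `ε = 1e−12` throughout.

**Feature roster.** 8 GLCM + 5 NGTDM + 6 GLZM + 5 shape = 24 named
features.  The five shape features are volume, surface area,
surface-to-volume ratio, sphericity and box-counting fractal dimension;
names, not positions, are the public contract.

**Surface area** is measured on a marching-cubes isosurface at the 0.5
level after smoothing the binary mask with a 0.6-voxel Gaussian.  Meshing
the raw binary mask quantizes vertices to mid-voxel planes and
overestimates smooth surfaces by 7–8%; the smoothed level set is within
~2% of the analytic value for digitized spheres of radius ≥ 8 voxels.  The
cost is rounding of perfectly sharp edges (a solid cube's area reads ~4%
low, its sphericity ~0.84 instead of the ideal 0.806); tumors are smooth
bodies, so the trade favors the smoothed estimate.  Masks too small for
the smoothed field to reach the iso-level fall back to the raw binary mesh.

**Fractal dimension** is the least-squares slope of `log N(box)` vs
`log(1/size)` over dyadic box sizes covering the 6-connectivity surface
voxels; ROIs too small to support two scales return 2.0 (surface-like).

## Survival analyses

**Imputation.** A censored patient with last-visit time `c` receives
`mean{t_j : event_j = 1, t_j ≥ c}` — the mean survival of deaths no earlier
than `c`.  A censored time beyond the last death is kept as-is (no
qualifying death exists); imputation therefore never decreases a time and
is the identity on fully-observed cohorts.  All three analyses call this
one function on identical per-group inputs, so they share a single
imputation result by construction.

**Screen.** Spearman's ρ with average ranks for ties, two-sided p from the
t-approximation; a constant vector yields (ρ=0, p=1).  The Holm–Bonferroni
family is *per grouping variable*: all levels × all screened variables
(24 features + age), e.g. m=100 for four subtypes.  Groups with fewer than
3 patients are skipped with a warning and do not enter the family.  An
uncensored-only mode (deaths only, no imputation) provides the sensitivity
check that imputation is not manufacturing associations.

**Median split / log-rank.** Arms are `feature < median` vs `≥ median`
within the group; with heavy ties the split can degenerate — such cells are
flagged and excluded from the corrected family rather than tested.  The
log-rank statistic processes all deaths tied at a time against the same
risk set; `chi2 = (O_A−E_A)²/V` on one degree of freedom.  The hazard ratio
is the observed/expected ratio `(O_A/E_A)/(O_B/E_B)` from the log-rank
table — it needs no extra model; a univariate Cox fit is available behind
`hr_method="cox"` and agrees to within estimator differences.  KM medians
use the standard convention (smallest t with `S(t) ≤ 0.5`, infinite when
the curve never crosses).  Report tables carry day values and a
month-formatted convenience column (30.44 d/month).

**Prediction.** Labels: short = imputed survival strictly below the group
median, long = at or above (near-even classes by construction).  The forest
is bagging of scikit-learn decision trees — bootstrap resamples of
training-set size, `floor(sqrt(p))` candidate features per split, unlimited
depth, class-probability votes averaged — built tree-by-tree so each tree's
out-of-bag rows remain available.  Cross-validation uses a plain random
even-sized partition (not label-stratified), the same folds for the
TNM-only and Combined models so the comparison is paired; fold AUCs are
averaged, and mean ROC curves average TPR on a fixed 101-point FPR grid.
Folds containing one class are excluded from the mean with a warning.  The
Combined set is the 5 clinical variables + 24 radiomic features (29);
`radiomics_only=True` drops the clinical block.  One integer seed drives
folds, bootstraps and split randomness; runs are bit-reproducible.

A consequence of balanced-by-design labels with unstratified folds: when
features carry no signal, training and held-out class priors anti-correlate
and cross-validated AUC sits slightly *below* 0.5 rather than at it.  This
is a property of the evaluation design, visible in the complement-group
results; stratification (available via the folds argument) removes it.

**Importance.** Per fold and per tree, each feature's values are permuted
among that tree's out-of-bag rows and the increase in OOB
misclassification error recorded; per-feature increases are averaged over
trees, divided by their standard deviation across trees, and averaged
across the 10 folds.  Features a fold's ensemble never uses get 0.

## Synthetic cohort generator

The generator's defaults define the study conditions:

- **Cohort composition**: 277 patients; subtype, T, N, M and stage drawn
  independently from proportions emulating a 315-patient NSCLC cohort
  (LCC 100 : SCC 90 : ADC 31 : NOS 56, T2-heavy, mostly M0, stage IIIb
  largest).  Independence across staging variables is a simplification —
  real TNM variables are mutually constrained.
- **Phantoms**: ellipsoids with diameter drawn by T stage (T1 16–28 mm,
  T2 30–70 mm, T3/T4 larger), mildly anisotropic axes, on a 3 mm isotropic
  grid.  In-mask texture is white noise smoothed with kernel width
  `(1−h)·3.0 + h·0.5` voxels, unit-variance rescaled: `h = 0` coarse and
  smooth, `h = 1` fine-grained.  The 3 mm grid keeps cohort-scale
  extraction desk-scale; since all texture features are rank statistics of
  the quantized field, only the ordinal texture structure matters, which
  the correlation-length mechanism preserves.  Intensities make no attempt
  at Hounsfield realism, and no CT noise model is simulated.
- **Survival**: exponential proportional hazards,
  `log λ = log λ0 + β·h·1[planted subgroup] + stage offsets`
  (I/II/IIIa/IIIb → 0/0.2/0.4/0.6), baseline median 1500 days.  Censoring
  is an independent exponential whose rate is solved (bisection on the
  cohort-average `μ/(λ+μ)`) to hit the 34% censoring target.
- **Planted effect**: β = 2.2 per unit `h` in the LCC subgroup.  This value
  is calibrated analytically, not fitted: with `h ~ U(0,1)` the hazard
  ratio between median-split arms is ≈ `exp(β/2)` ≈ 3 and the Spearman
  ceiling between `h` and exponential survival is ≈ 0.47 — the
  moderate-correlation, HR ≈ 3 regime the analysis pipeline is designed to
  detect.  Materially smaller couplings (e.g. β = 1, ceiling ≈ 0.24) are
  mathematically incapable of clearing a 100-test Holm threshold at
  n ≈ 100 for *any* feature, however good the extraction.

What passing the synthetic suite shows: the matrices and statistics are
computed correctly, the pipeline recovers a known monotone texture–hazard
coupling end-to-end through real feature extraction, error rates are
controlled under the null, and effect sizes on the planted cohort land in
the intended regime.  What it does not show: performance on real CT
(scanner effects, delineation variability, non-ellipsoidal morphology,
correlated staging variables, non-exponential hazards).

## Problem sizes

Default analysis scales: 277-patient planted cohort; 300-patient null bank
with 100 survival replicates for family-wise calibration and 3 replicates
for chance-level AUC; forests of 500 trees × 10 folds.  These sizes make
the full validation suite and the reproduction script each run in minutes
on a single CPU while keeping every statistical check at the cohort scale
the analyses are meant for.

## Known limitations

- The feature roster fixes one defensible 24-feature set; other radiomics
  software enumerates different (larger) families, so absolute feature
  values are comparable only within this package.
- The O/E hazard-ratio estimator is biased toward 1 relative to the Cox
  MLE in small samples; both are exposed.
- Box-counting dimension on small tumors (< ~16 voxels extent) has too few
  scales to be meaningful and returns values near 2 by construction.
- The null-calibration design redraws survival on a fixed feature bank;
  it measures family-wise error conditional on one realistic feature
  correlation structure, not marginalized over imaging randomness.
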