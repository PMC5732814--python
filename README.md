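# radsurv

Radiomics–survival analysis for CT tumor imaging: extract texture and shape
features from 3D tumor volumes and relate them to patient survival.

The package is aimed at quantitative-imaging researchers studying
non-small-cell lung cancer (NSCLC)-style cohorts: each patient contributes a
CT volume, a delineated gross tumor volume (GTV) mask, clinical staging
(TNM, overall stage, histological subtype) and right-censored overall
survival.  The question it answers is whether computable tumor phenotype —
heterogeneity of grey-level texture, size, surface complexity — carries
prognostic information within clinically defined subgroups, beyond staging
alone.

## What it computes

**24 radiomic features per tumor.** Image intensities inside the GTV are
uniformly resampled to `Ng = 32` grey levels; three texture matrices are
built in full 3D:

- **GLCM** `P(i,j)`: co-occurrence of level pairs over the 13 unique
  3D directions (symmetric, counts merged before normalization) — energy
  `Σp²`, entropy `−Σp log₂p`, contrast `Σ(i−j)²p`, dissimilarity `Σ|i−j|p`,
  homogeneity `Σp/(1+(i−j)²)`, correlation, variance, autocorrelation;
- **NGTDM** `s_i = Σ|i − A|` over voxels of level `i` with 26-neighborhood
  average `A` — the Amadasun–King coarseness, contrast, busyness,
  complexity and strength;
- **GLZM** `P(i,z)`: counts of 26-connected same-level zones by level and
  size — small/large zone emphasis, grey-level non-uniformity, zone size
  non-uniformity, zone percentage, large zone / high grey emphasis;

plus five mask-only shape features: volume, mesh surface area,
surface-to-volume ratio, sphericity `π^{1/3}(6V)^{2/3}/A`, and a
box-counting fractal dimension of the tumor surface.

**Three survival analyses per grouping variable** (subtype, T, N, M, stage):

1. *Correlation screen* — censored patients are imputed with the mean
   survival of deceased patients who lived at least as long as their last
   visit; Spearman's ρ between each feature (plus age) and imputed survival
   is tested per subgroup, Holm–Bonferroni-corrected over the grouping-wide
   family (e.g. 4 subtypes × 25 variables = 100 tests).
2. *Median-split Kaplan–Meier* — each feature dichotomizes its subgroup at
   the median value; arms are compared with the log-rank test, the hazard
   ratio estimated from the observed/expected event ratio, with the same
   family-wise correction.
3. *Random-forest prediction* — patients are labeled short/long survivors
   (below vs at-or-above the median imputed survival) and a 500-tree bagged
   forest is evaluated by 10-fold cross-validated AUC, comparing clinical
   staging alone (age, T, N, M, stage) against staging + radiomics on
   identical folds; feature relevance via out-of-bag permutation
   importance, normalized by the between-tree standard deviation.

A synthetic cohort generator ties everything together: ellipsoidal tumor
phantoms whose internal texture heterogeneity `h ∈ [0,1]` is a smoothed
Gaussian random field, and an exponential proportional-hazards survival
model in which `h` raises the hazard (default: in the LCC subgroup only).
Because the coupling is routed through the latent `h` and must survive the
real extraction pipeline, the generator provides an end-to-end test bed
with known ground truth.

## Worked example

```python
from radsurv import SimulationConfig, screen_group, simulate_cohort

cohort = simulate_cohort(SimulationConfig(n_patients=277, seed=1))
screen = screen_group(cohort, "subtype")
print(screen[screen["significant"]][["group", "feature", "rho", "p_adj"]])
```

prints (run `python examples/survival_screen.py`):

```
group                  feature       rho    p_adj
  LCC              glcm_energy  0.362666 0.024326
  LCC             glcm_entropy -0.379505 0.011866
  LCC            glcm_contrast -0.413617 0.002491
  LCC       glcm_dissimilarity -0.413426 0.002491
  LCC         glcm_homogeneity  0.412762 0.002546
  LCC         glcm_correlation  0.415925 0.002244
  LCC         ngtdm_complexity -0.477166 0.000078
  LCC glzm_small_zone_emphasis -0.394003 0.006199
  LCC     glzm_zone_percentage -0.348036 0.043908
```

All significant cells sit in the LCC subgroup — where the effect was
planted — with moderate correlations (|ρ| 0.35–0.48); negative signs mean
finer-textured (more heterogeneous) tumors go with shorter survival.  The
median split on `glzm_zone_percentage` in the same subgroup
(`examples/median_split_km.py`) gives arm medians of 642 vs 243 days and a
hazard ratio of 2.15 (log-rank p = 7e-4), and the paired forest comparison
(`examples/predict_survival_group.py`) yields mean AUC 0.537 (staging only)
vs 0.663 (staging + radiomics).

Each script in `examples/` demonstrates one capability; the `radsurv` CLI
(`simulate`, `extract`, `screen`, `km`, `predict`, `study`) exposes the
same stages for shell pipelines on NIfTI/NRRD + CSV inputs.

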