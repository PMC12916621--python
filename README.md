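# perifc — perilesional functional connectivity after glioma resection

`perifc` quantifies, from a postsurgical resting-state fMRI scan, how strongly
the tissue immediately surrounding a surgical resection cavity is coupled to
the rest of the brain **relative to its mirrored contralateral homologue**,
and relates that scalar to overall survival and functional (Karnofsky
Performance Status, KPS) outcome in a small cohort.  It is aimed at
neuroimaging researchers studying prognosis after glioma surgery, and ships
with a synthetic-cohort generator so the entire analysis is runnable and
testable without access to patient data.

## The metric

For each subject with a 4D BOLD series, a binary resection mask and a brain
mask on one grid:

1. **Preprocessing.**  Drop the first 5 volumes; flag frames whose framewise
   displacement (Euclidean norm of the translation increment) exceeds
   0.3 mm; smooth with a 6 mm-FWHM Gaussian using mask-normalized weights
   over the cavity-excluded brain; remove — in one least-squares projection
   on the retained frames — an intercept, linear trend, the 6 motion
   parameters, ventricle and white-matter signals, and sine/cosine terms at
   every frequency outside 0.005–0.1 Hz.  The global signal is never
   removed.
2. **Masks.**  Perilesional shell `P = (dilate³(R) \ R) ∩ B` (3 iterations of
   6-connected dilation of the resection mask `R`, intersected with brain
   `B`); contralateral homologue = `P` reflected across the mid-sagittal
   grid plane, ∩ `B`; target mask `T = B \ R` (cavity-excluded brain).
3. **Connectivity.**  For every seed voxel `v ∈ P` and its mirror `v′`:
   average the BOLD series over a 5 mm-radius sphere ∩ `T`, Pearson-correlate
   with every voxel of `T`, Fisher-transform (`z = atanh r`), and average
   over `T`.  The difference-map entry is

   `Δz(v) = mean_T z(v) − mean_T z(v′)`

   and the **subject metric** is `m = mean_{v∈P} Δz(v)`.  `m < 0` means the
   perilesional shell is less coupled to the brain than its mirror image.
4. **Cohort statistics.**  Median-survival split (living subjects count as
   long survivors), Kolmogorov–Smirnov normality screen, two-tailed
   Mann–Whitney U (exact by full enumeration at these sample sizes), pooled-SD
   Cohen's d, Spearman ρ between `m` and the 6-month KPS change, and OLS
   `ΔKPS ~ 1 + m + age + sex + grade + tumor volume`.
5. **Prediction.**  Leave-one-out Gaussian-kernel SVM classification of the
   15-month survival split (long = 1) and SVM/linear regression of ΔKPS, with
   fold-internal standardization and fixed hyperparameters (C = 1,
   γ = 1/n_features).

## Worked example

The `analysis/` scripts run the whole study on a simulated 12-subject cohort
(six subjects with a large planted perilesional coupling deficit and short
survival, six with a small deficit and long survival):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_connectivity_maps.py
python analysis/03_group_statistics.py
python analysis/04_outcome_prediction.py
```

which prints (abridged):

```
simulated cohort (seed 0): 12 subjects
  short-survival group: n=6, survival 6.3 +/- 3.6 mo, deficit 0.53 +/- 0.09
  long-survival group:  n=6, survival 34.3 +/- 10.5 mo (5 alive), deficit 0.09 +/- 0.07
...
sub-01: metric=-0.4108 (276 seed pairs, 2 frames censored)
...
median-survival split at 18.5 mo: 6 short vs 6 long
  metric short -0.2155 +/- 0.1095, long -0.0147 +/- 0.0124
  Mann-Whitney U=0, two-tailed p=0.0022; Cohen's d=-2.58
  Spearman rho(metric, KPS change) = 0.923 (p=1.9e-05, n=12)
LOOCV survival classification: accuracy 83%  (TPR 100%, TNR 67%, ...)
LOOCV KPS regression (svm_rbf): |error| 10.91 +/- 10.24, ...
```

Reading this: every subject's metric is negative (the shell is less connected
than its mirror), the short-survival group's metrics are far more negative
than the long group's (U = 0 is complete separation; p = 0.0022 is the exact
two-tailed floor for 6 vs 6), and the metric tracks 6-month functional change
almost monotonically.  Tables land in `results/`, an example difference-map
NIfTI in `scratch/`.

A `perifc` console script exposes the same pipeline for file-based data:
`perifc simulate --out DIR`, `perifc run-subject --config cfg.yaml
--subject ID --out DIR`, `perifc run-cohort --config cfg.yaml --out DIR`.
Subject inputs are NIfTI volumes (BOLD, resection mask, brain mask) plus TSV
motion (6 columns) and nuisance (ventricle, white-matter) traces; see
`tests/test_pipeline.py` for a config example.

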