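# Methods

This note documents the model, the tunable parameters, the synthetic-data
generator, and the numerical and design choices behind `perifc`.

## The connectivity difference metric

The quantity of interest is a subject-level scalar comparing the whole-brain
functional coupling of the perilesional shell (tissue within a few voxels of
the resection cavity) with that of its mirrored contralateral homologue.
For a seed voxel `v`, the seed series is the unweighted mean BOLD series over
a sphere of radius 5 mm centred on `v`, intersected with the cavity-excluded
brain mask `T = brain \ resection`.  Its whole-brain connectivity is the mean
over `T` of the Fisher-transformed Pearson correlation between the seed
series and each target voxel's series.  The per-voxel difference-map entry is
the perilesional value minus the contralateral value, and the subject metric
is the mean entry.  By linearity the mean over targets of the voxelwise
z-difference equals the difference of the two mean-z values, which is what is
computed (and asserted in tests).

Conventions that make the subtraction well-posed:

* **One common target mask** `T` for both the perilesional and contralateral
  seeds.  Using separate targets would confound the difference with target
  composition.
* **Zero-variance target voxels contribute z = 0** and are tallied, so both
  sides always average over identical voxel sets.
* The seed's own sphere voxels are *not* excluded from the target; the small
  self-correlation bias is common to both sides and largely cancels in the
  difference.
* Seeds whose mirrored voxel falls outside the brain (or inside the
  resection, where no seed series is defined) are excluded and counted as
  unpaired — a QC output, not an error.
* Mirroring is the grid reflection `x -> nx - 1 - x` along the left-right
  axis.  This presumes images already normalized to a grid-aligned symmetric
  space; no nonlinear symmetric registration is attempted.

Sign convention: metric < 0 means the perilesional shell is *less* coupled to
the brain than its mirror image.

## Preprocessing

| parameter | default | unit | role |
|---|---|---|---|
| `n_drop` | 5 | frames | discard non-steady-state start of run |
| `censor_threshold_mm` | 0.3 | mm | framewise-displacement censor |
| `band_hz` | (0.005, 0.1) | Hz | retained frequency band |
| `fwhm_mm` | 6 | mm | Gaussian smoothing kernel |
| `dilation_iterations` | 3 | voxels | shell thickness (≈ 1 cm in-plane) |
| `sphere_radius_mm` | 5 | mm | seed ROI radius |
| `survival_cutoff_months` | 15 | months | long-survival coding for the classifier |

Framewise displacement is the Euclidean norm of the frame-to-frame change of
the three translation parameters; rotations are ignored because no
rotation-radius convention is assumed (a `censor_use_rotations` switch exists
in the config surface for future use).  Censored frames are **deleted**, not
interpolated, and stay excluded from every downstream correlation.

Temporal filtering and nuisance removal are one simultaneous least-squares
projection per voxel, fit on the retained frames only, onto the complement of
the span of: intercept, linear trend, 6 motion parameters, ventricle signal,
white-matter signal, and sine/cosine pairs at every DFT frequency
`k / (N · TR)` outside the pass band (cosine only at the Nyquist bin for even
N).  Sequential filter-then-censor re-introduces artifact from censored
frames into their neighbours; a joint projection is well defined on the
irregular time grid censoring leaves.  The whole-brain global signal is never
a regressor (its removal is known to induce spurious anti-correlations).  The
projection is idempotent and exact on signals inside the design span; both
properties are tested.  Rank-deficient designs fail with the collinear
columns named.

Smoothing uses an anisotropy-corrected sigma per axis,
`sigma_axis = FWHM / (2 sqrt(2 ln 2)) / voxel_mm_axis`, with mask-normalized
weights over the **cavity-excluded** brain mask: the smoothed value at a
voxel is the Gaussian average of in-mask neighbours renormalized by the
smoothed mask, so the cavity's zeros (and out-of-brain zeros) never smear
into tissue.  Smoothing precedes the regression so nuisance is not re-mixed
across voxels after removal.

Ventricle and white-matter signals are *inputs* (mean series over
caller-supplied regions, or explicit TSV columns); tissue segmentation is out
of scope and the synthetic generator supplies them directly.

## Mask geometry

"Dilated by three neighboring voxels" is read as 3 iterations of 6-connected
(face-neighbour) binary dilation — an L1 ball of radius 3 for a point seed —
clipped to the grid, with the brain intersection applied afterwards rather
than geodesically; 18/26-connected structuring elements are available as
options.  Tumor volume is computed from the resection mask (voxel count ×
voxel volume), a proxy for the clinical tumor volume, since the resection
mask is the only volumetric input the pipeline has.  Contralateral validity
(the homologue being lesion-free) is the caller's responsibility; the
pipeline reports the contralateral∩resection overlap count per subject.

## Cohort statistics

* Median-survival split over observed months; living subjects' elapsed time
  enters the median and living subjects always join the long-survival group.
  No censoring-aware survival model (Kaplan–Meier, Cox) is fit — group
  membership is the survival summary.
* KPS change = 6-month KPS − preoperative KPS, with two special cases: death
  before 6 months scores 0 at follow-up (change = −KPS_pre), and a living
  subject without a 6-month score is excluded from KPS analyses only.
* Mann–Whitney U is two-tailed with midranks; the p-value is exact by full
  enumeration of all C(n_a+n_b, n_a) assignments when n_a+n_b ≤ 14 (924
  assignments for the 6+6 design), otherwise the tie-corrected,
  continuity-corrected normal approximation.
* Spearman's ρ is the Pearson correlation of midranks; exact permutation p
  for n ≤ 8, else the t-approximation with n−2 df.
* Cohen's d uses the pooled-SD formula with sample (n−1) variances.
* The normality screen is the textbook one-sample KS test against a normal
  with the sample mean and SD.  The Lilliefors correction is deliberately
  omitted; consequently the screen is conservative (it reliably flags strong
  skew, but mild deviations such as a uniform shape often pass at n ≈ 200).
* The outcome model is OLS `ΔKPS ~ 1 + metric + age + sex + grade + volume`
  with sex coded female = 0 / male = 1 and WHO grade as a numeric 1–4 score.
  Covariates constant in the fitted subset (grade in a grade-homogeneous
  subgroup; tumor volume in the default fixed-geometry synthetic cohort) are
  dropped with a warning rather than failing.
* All tests are two-sided at α = 0.05; no multiple-testing correction is
  applied across the exploratory subsets.

## LOOCV prediction

Each subject is summarized by five features of their difference map: mean
perilesional z, mean contralateral z, the subject metric, the SD of the map
entries, and the fraction of negative entries (`metric_only` restricts to the
scalar).  A dozen subjects cannot support higher-dimensional features.
Classification uses an RBF-kernel SVM with fixed C = 1 and kernel width
1/n_features on standardized inputs; regression uses RBF SVR or linear
regression on identical folds, with the target standardized per fold as well.
Standardization statistics and the model fit use only the n−1 training
subjects of each fold; there is no inner hyperparameter search (at n = 12 any
tuning loop is leakage-prone).  Classification is by decision-function sign,
with long survival (≥ 15 months, or still alive) as the positive class.

A note on leave-one-out nulls: with perfectly balanced labels, the held-out
subject's class is always the training minority, so an uninformative
classifier scores *below* chance, not at it.  The null tests therefore use an
unbalanced composition, where the majority-fraction baseline is the correct
reference.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes, at a
scale where the full 12-subject study runs in a few seconds:

* grid 24 × 24 × 16 voxels of 3.75 × 3.75 × 4 mm, TR 2.4 s, 120 frames
  before dropping — the scanner's voxel geometry at a quarter of the matrix,
  leaving ≈ 280 perilesional seeds per subject;
* a left-right symmetric ellipsoidal brain; a spherical resection cavity of
  exact zeros on one hemisphere, strictly lateral so the mirrored shell is
  lesion-free;
* one shared band-limited (0.01–0.08 Hz) latent network series `g(t)`; every
  brain voxel is `beta · g(t)` plus iid Gaussian noise (SD 1), with
  `beta_c = 0.75` on the contralateral shell, `beta_c − delta` on the
  perilesional shell (`delta` is the planted deficit), and `beta_c/4`
  elsewhere in brain;
* ventricle/white-matter confounds added globally with known weights, so the
  nuisance regression has real structure to remove;
* a near-zero motion trace with level shifts at chosen frames producing
  displacement spikes > 0.3 mm — the censoring round-trip (planted spikes =
  censored frames) is asserted;
* clinical records: short-survival subjects carry deficits of 0.5–0.9 ·
  beta_c and lognormal survival under 15 months; long-survival subjects carry
  0–0.25 · beta_c and ≥ 15 months (alive with probability 2/3).  The 6-month
  KPS change follows a strictly monotone link in the analytic expected
  metric, `a + b · sign(m)|m|^0.5` with a = 5, b = 150, Gaussian noise SD 4,
  quantized to the 10-point KPS scale.  The sub-linear exponent keeps
  small-deficit subjects spread across more than one KPS step (a linear link
  collapses the long-survival group onto a single tied level, an artifact of
  the quantized scale, not of the physiology).  Subjects who die before the
  6-month follow-up have change = −KPS_pre by definition; the generator
  places their preoperative KPS at the rounded negative of the drawn change
  target (terminal-decline convention) so the cohort-level monotone structure
  survives.

The analytic expected metric used by the outcome link treats the target as
background-coupled voxels and the seed as a 7-voxel sphere average; it
ignores smoothing and shell-target contributions, so it is a monotone index
of the deficit, not an unbiased prediction of the recovered value (the
recovered metric is larger in magnitude).

What the generator does **not** emulate — and hence what passing tests do not
establish about real data: hemodynamic response shape, physiological noise
spectra, scanner drift, partial-volume effects, multi-network topology,
registration/normalization error, asymmetric brains, lesions near the
midline, and any real relationship between imaging and outcomes.  The
synthetic links from deficit to survival and KPS are generative conveniences
that make the pipeline's recovery properties testable; nothing in the
analysis code knows about them.

By default all cohort subjects share one cavity geometry (so the planted
deficit is the only physiological difference and tumor volume is constant —
the outcome model then drops it); `make_cohort(..., vary_cavity=True)`
jitters cavity radius and centre when a varying volume covariate is wanted.

## Numerical choices

* Correlations are clipped to |r| ≤ 1 − 1e-7 before `atanh`, so perfect
  correlations map to a finite ceiling (≈ 8.4) instead of infinity.
* Grid equality between volumes is enforced to 1e-3 mm per axis — loose
  enough for header float noise, tight enough to catch real mismatches.
  Mask files are thresholded at 0.5 on read, making fractional (resampled)
  values well-defined.
* Design-matrix rank is checked by SVD with a 1e-10 relative threshold;
  failures name the collinear columns via QR.
* Volumes are written as float32 NIfTI-1 (round-trip accurate to ~1e-6);
  all in-memory computation is float64.
* Determinism: every random quantity flows from a `numpy` `SeedSequence`;
  the same seed reproduces a cohort bit-for-bit, and reports embed the
  resolved configuration and its SHA-256 hash.

## Known limitations

* Spatial registration, normalization and segmentation are out of scope:
  inputs must already share a grid whose mid-sagittal plane is a grid plane.
* The exact-zero symmetry null uses a deliberately unphysiological
  construction (midline-symmetric resection) to isolate the mirror-symmetry
  property of the difference map.
* The normal-approximation branch of the Mann–Whitney test and the
  t-approximation branch of Spearman's p are asymptotic; they are only used
  beyond the enumeration limits (14 and 8 observations respectively).
* At n = 12 the LOOCV estimates have high variance; the fixed-hyperparameter
  SVM is a deliberate floor, not a tuned ceiling.
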