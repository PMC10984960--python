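# Methods

## Scope and model

`sbmorph` implements a source-based-morphometry (SBM) analysis chain for
predicting amyloid-beta (Aβ) PET positivity in a mixed memory-clinic
population (AD, MCI, FTLD, CBS, PSP, psychiatric disorders, healthy
controls). The pipeline consumes already-preprocessed GM volumes — i.e.
segmented, MNI-normalized, modulated, smoothed maps on a regular grid
(the common template grid is 91 × 109 × 91 at 2 mm isotropic; desk-scale
work uses 24 × 28 × 24). Segmentation, normalization, PET acquisition and
visual Aβ reads, and wet-lab APOE genotyping are out of scope.

Stages:

1. **Masking and flattening** (`sbmorph.volumes`). Volumes are reduced to
   the voxels of a boolean brain mask and stacked into a subjects × voxels
   matrix, C order, exactly invertible on masked cells. Masks are
   user-supplied NIfTI, all-true, or thresholded cohort-mean images;
   atlas-based masking is not reimplemented.
2. **Decomposition** (`sbmorph.decompose`). Fixed-point ICA (scikit-learn
   FastICA) on the voxel-wise mean-centered matrix, with voxels as
   observations, yields K spatial component maps. Subject loadings β are
   then re-estimated by no-intercept OLS of each centered image on the
   maps (`I_GM = Σ_k β_k IC_k`), so loadings are defined identically for
   fitting-cohort and held-out subjects. β behaves as a "weighted total
   gray matter volume" of each component's pattern.
3. **Classification** (`sbmorph.classify`). RBF-SVM, stratified fivefold
   CV, grid search over (C, gamma, K). All metrics pool out-of-fold
   predictions.
4. **Interpretation** (`sbmorph.explain`). Kernel-SHAP attributions of the
   decision score, fold-wise, averaged into a feature ranking.
5. **Clinical statistics** (`sbmorph.stats`). t-tests, chi-square,
   correlation tables, ANOVA, Games–Howell.
6. **Interfaces** (`sbmorph.io`, `sbmorph.pipeline`, `sbmorph.cli`).
   NIfTI-1/CSV/YAML/JSON I/O and an end-to-end seed-deterministic report.

## Numerical conventions of the decomposition

ICA leaves scale, sign, and order of components indeterminate; the
following conventions make results reproducible bit-for-bit for a seed:

- **Centering.** The voxel-wise mean image over the fitting subjects is
  subtracted before ICA and before every OLS projection, and stored as
  `train_mean`. A constant image added to every subject is therefore
  absorbed on refit.
- **Map estimation.** FastICA additionally removes each subject's mean
  over voxels; the returned sources therefore live in a doubly-centered
  space and cannot reconstruct the centered data exactly. The spatial maps
  are instead re-estimated as `pinv(mixing) @ centered`, which spans the
  centered data's row space: on a noise-free cohort with K equal to the
  true source count, reconstruction from (loadings, maps, train_mean) is
  exact to machine precision.
- **Scale.** Each map is normalized to unit variance over masked voxels,
  making β values comparable across components (and making the z-scored
  display maps nearly the raw maps).
- **Sign.** Maps are flipped so their skewness over masked voxels is
  non-negative (tie-break: the maximum-|weight| voxel is positive).
- **Order.** Components are sorted by descending variance of their subject
  loadings. Note this means the strongest *overall* mode is IC_1; the
  Aβ-associated component is identified scientifically — by its row in the
  correlation table — not by its index.
- **Convergence.** ICA non-convergence within `max_iter` (default 1000) is
  recorded on the result (`converged`, `n_iter`), not raised.
- **Degenerate inputs.** K above the subject-rank limit, all-constant
  subject rows, rank-deficient or near-singular map Grams (condition
  number > 1e12), and constant maps in z-scoring raise errors.

Z-maps (`zscore_component`) standardize one map over masked voxels,
retain z ≥ threshold (default 1.0), and fold back into a 3D grid for
NIfTI export; sub-threshold voxels are zeroed.

`component_stability` reruns the decomposition with different seeds and
reports per-component mean |correlation| after Hungarian alignment of maps
— a practical aid for choosing K beyond the CV grid search.

## Classification details

- **Feature blocks.** brain = the K loadings; demographics = age and sex
  (male = 1); cognition = MMSE, CDR global/sum, FAQ, LM I/II, ADAS-cog-J,
  WF category/initial, TMT A/B, JART (all administered tests — the named
  sets are configurable); APOE = any-ε4 indicator and ε4 allele count.
  Named sets: brain, cognition, apoe, brain+cognition, brain+apoe, and ALL
  (brain + demographics + cognition + APOE). Demographics appear only in
  ALL, matching the reporting layout, which has no demographics-only row.
- **Tuning modes.** `nested` (default): within each of the 5 outer
  training folds, an inner stratified CV (3 splits by default, a cost
  choice — the outer folds stay at 5) refits the ICA per candidate K,
  refits imputation/scaling, and scores every (K, gamma, C) cell; the best
  cell (ties broken by grid order: K, then gamma, then C, first listed
  wins) is refit on the full training fold. No statistic of held-out
  subjects reaches the fitted model — enforced by a test that corrupts
  test-fold volumes after fold assignment and checks the fitted SVM is
  bit-identical. `pooled`: ICA once on all scans per K, plain fivefold
  grid search maximizing CV accuracy; reproduces the original protocol in
  which decomposition preceded cross-validation.
- **Default grids** span decades 10⁻³…10³ for C and gamma and K = 2…12,
  covering the reference optimum (C = 0.01, gamma = 100, K = 7); tests and
  the acceptance script use reduced grids (C, gamma ∈ {0.01, 1, 100},
  K ∈ {3, 5, 7}) to keep desk-scale runs fast.
- **Preprocessing per fold.** Training-fold median imputation (with
  companion missing-indicator columns created for any feature containing
  missing values) and z-standardization, refit inside every fold.
- **Metrics.** accuracy = (TP+TN)/(TP+TN+FN+FP), sensitivity = TP/(TP+FN),
  specificity = TN/(FP+TN), PPV = TP/(TP+FP), NPV = TN/(FN+TN), reported
  as percents to 1 dp; a zero-denominator ratio is NaN and prints "N/A",
  never 0. AUC comes from pooled out-of-fold decision scores (trapezoidal)
  with a seeded 2,000-resample percentile bootstrap CI (resamples with one
  class are skipped). Diagnosis-subset reports reuse the same out-of-fold
  predictions without refitting, so disjoint subsets aggregate additively
  at the count level.

## Shapley attributions

The SHAP variant is model-agnostic kernel estimation: for each explained
subject, feature coalitions are enumerated exhaustively when 2^M fits the
coalition budget (default 2¹¹ — exact for M ≤ 11, which covers all
brain-only models) and otherwise sampled in complementary pairs with
probability proportional to the Shapley kernel weight of the coalition
size. Absent features are marginalized over a background of at most 100
training-fold rows (seeded subsample). Attributions solve the
kernel-weighted least squares under the efficiency constraint
`base + Σφ = f(x)`; under full enumeration the solution is the exact
Shapley value of the marginalized value function, and local accuracy holds
to machine precision (the test tolerance is 10⁻² of the score SD to admit
the sampled regime). Attributions explain the SVM decision score (signed
distance), not the hard label: positive φ push toward Aβ-positivity.
Fold-averaged importance is the mean over folds of mean |φ| over each
fold's held-out subjects; when nested tuning selects different K per fold,
features are averaged over the folds that contain them.

## Statistical battery

- `ttest_from_summary` / `ttest_raw`: two-tailed two-sample t. The default
  pools variances (df = n₁+n₂−2) because published summary tables of this
  kind are computed that way; Welch (`equal_var=False`) is available. The
  raw-data version is defined as the summary version applied to sample
  mean/SD/n — an exact identity, tested as such.
- `chi_square`: Pearson, no continuity correction by default
  (configurable); zero-margin rows/columns are dropped with a warning.
- `correlation_table`: Pearson r per (clinical variable, component);
  binary variables enter as 0/1, making their cells point-biserial.
  Bonferroni correction across the table's variable dimension within each
  component column (family size = number of variables, configurable,
  default 16 rows: sex, age, education, 12 cognitive scores,
  Aβ-positivity); flags at α = 0.05 and 0.01.
- `anova_oneway`: standard F with df (k−1, N−k); at k = 2, F = t² of the
  pooled t-test (checked as an identity).
- `games_howell`: per pair, Welch SE √(s²ᵢ/nᵢ + s²ⱼ/nⱼ),
  Welch–Satterthwaite df, q = |Δmean|/SE·√2, p from the studentized-range
  distribution with the full group count k. At k = 2 it reduces to the
  two-tailed Welch t-test (agreement < 10⁻⁴, tested); the implementation
  also matches pingouin's to 10⁻⁶ on random data. Zero-variance pairs
  report NaN.

## The synthetic-cohort generator

Each subject's volume is `Σ_k loading[s,k] · source_k + N(0, noise_sd)`.
Sources are isotropic Gaussian blobs (default extent 3 voxels on the
24 × 28 × 24 grid) rejection-placed with pairwise peak separation
≥ 3 × extent, which keeps pairwise map correlations below 0.2. Loadings
are standard normal, with two planted structures:

- the **discriminative source** (index 0): loadings of Aβ-positive
  subjects are shifted by −`loading_shift` within-group SDs. The default
  1.24 is calibrated analytically so the population point-biserial
  correlation with Aβ status is −0.52 at the default 38.1% prevalence,
  the reference association strength of the AD-related component;
- the **age-linked source** (index 1): loadings are mixed with
  standardized age to a population correlation of −0.556, the reference
  aging-pattern association.

Labels are assigned deterministically — exactly `round(n · fraction)`
positives, the assignment shuffled by the seed — so counts are exact
(45/118 = 38.1% by default). Diagnoses are drawn per label from the
reference joint distribution (e.g. 21/24 AD patients positive, all PSP
and psychiatric patients negative); sex per group (53% / 55% male);
APOE genotypes per group (ε4/4 only among positives, ε2 alleles only
among negatives). Cognitive scores and age are drawn independently per
variable from per-group normal distributions matching the reference
cohort's mean ± SD, then clipped at their floors (0 for all test scores;
MMSE additionally capped at 30).

What the generator does **not** emulate: between-variable covariance of
cognitive scores (published tables give none, so scores are independent
within group — real batteries correlate strongly); scanner artifacts,
bias fields, segmentation or registration error; longitudinal structure;
nonlinear atrophy topography (sources are additive blobs). Clipping at
score floors biases the means of heavily censored scales (e.g. FAQ,
TMT-A among negatives) away from the configured values; the calibration
test therefore checks sample means against the clipped-normal population
mean computed by quadrature, not against the raw configured mean.
Consequently, passing tests demonstrate the *pipeline's* correctness on
data with the assumed linear-mixture structure — not that real GM data
satisfy that structure.

## Problem sizes and expected behavior

Tests and the acceptance script run on the 24 × 28 × 24 grid (16,128
voxels, all-true mask) with 60–120 subjects, reduced hyperparameter grids,
and 10 seeded replicates for ranking checks; the full suite completes in
about a minute. With the planted effect at 2.0 within-group SDs the
Bayes-optimal accuracy of the brain-only classifier is Φ(1) ≈ 84% for
balanced classes (≈85% at 38.1% prevalence), so nested out-of-fold
accuracies near 85% indicate the classifier is extracting essentially all
available signal; observed values fluctuate a few points around that
ceiling across seeds. Under label permutation, accuracy falls into the
binomial null band. The headline real-data results of the reference
analysis require the original 118-subject MRI/PET dataset and are not
reproducible from synthetic cohorts; the pipeline's property checks are
the intended validation.
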