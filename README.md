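# sbmorph

Source-based morphometry (SBM) analysis of structural brain MRI: predict
amyloid-beta (Aβ) PET positivity across mixed neurocognitive disorders from
gray-matter (GM) volume patterns, cognitive test scores, and APOE genotype.

The package is aimed at neuroimaging researchers who want a tested,
end-to-end, seed-deterministic implementation of the SBM + SVM + SHAP
workflow — including a synthetic-cohort generator with planted ground
truth, so every stage can be validated without access to patient data.

## The method

**Decomposition.** A cohort of spatially normalized, modulated GM maps is
masked, flattened to a subjects × voxels matrix, and decomposed by spatial
ICA (FastICA) into K independent component maps IC₁ … IC_K. Each subject's
image is then expressed through the spatial regression

```
I_GM = β₁ IC₁ + β₂ IC₂ + … + β_K IC_K
```

where the per-subject β loadings — ordinary least squares on the
mean-centered image, no intercept — act as "weighted total gray matter
volume" of each component's pattern. Maps are unit-variance over masked
voxels, sign-fixed by non-negative skewness, and ordered by descending
loading variance, so the decomposition is fully deterministic for a seed.

**Classification.** An RBF-kernel SVM predicts Aβ status from the β
loadings, optionally joined by demographics (age, sex), twelve
neuropsychological scores (MMSE, CDR, FAQ, Logical Memory I/II,
ADAS-cog-J, Word Fluency, TMT A/B, JART), and two APOE features (any-ε4
carrier, ε4 allele count). Stratified fivefold cross-validation pools
out-of-fold predictions; a grid search tunes C, gamma, and K. The default
`nested` mode refits ICA, scaling, and the grid search inside each
training fold (no test-fold leakage); `pooled` mode reproduces the
original all-scans-ICA protocol.

**Interpretation.** Kernel-SHAP attributions of the SVM decision score are
computed per fold against a training-fold background and averaged across
folds; positive values push toward Aβ-positivity.

**Statistics.** Group t-tests (from raw data or published mean ± SD
summaries), chi-square tests, component-by-clinical Pearson/point-biserial
correlation tables with Bonferroni control, one-way ANOVA, and the
Games–Howell post-hoc test.

## Worked example

```python
from sbmorph import (BrainMask, CohortConfig, CVConfig, compute_metrics,
                     correlation_table, crossval_fit_predict, decompose,
                     flatten_volumes, generate_cohort, mean_abs_importance,
                     shap_for_predictions)

# 1. simulate a 118-subject cohort with a planted AD-like GM pattern
cfg = CohortConfig(seed=0)           # defaults mirror the study conditions
volumes, table, truth = generate_cohort(cfg)
matrix = flatten_volumes(volumes, BrainMask.full(cfg.grid_shape))

# 2. source-based morphometry: 5 spatial ICs + per-subject beta loadings
comps = decompose(matrix, K=5, seed=0)
corr = correlation_table(comps.loadings, table,
                         variables=["age", "ab_positivity"])
r_ab = corr.xs("r", axis=1, level="stat").loc["ab_positivity"]
print("r(IC, Ab-positivity):", r_ab.round(3).to_dict())

# 3. nested cross-validated RBF-SVM on the IC loadings
cv = CVConfig(seed=0, tuning_mode="nested", n_inner=3,
              c_grid=(0.01, 1.0, 100.0), gamma_grid=(0.01, 1.0, 100.0),
              k_grid=(3, 5, 7))
preds = crossval_fit_predict(matrix, table, "brain", cv)
rep = compute_metrics(preds, seed=0)
print(f"accuracy {rep.accuracy:.1f}%  sensitivity {rep.sensitivity:.1f}%  "
      f"specificity {rep.specificity:.1f}%  AUC {rep.auc:.3f}")

# 4. fold-averaged SHAP importance of the decision score
shaps = shap_for_predictions(preds, seed=0)
print(mean_abs_importance(shaps, allow_union=True).round(3).head(3).to_string())
```

Output:

```
r(IC, Ab-positivity): {'IC_1': -0.037, 'IC_2': 0.08, 'IC_3': -0.431, 'IC_4': 0.034, 'IC_5': -0.142}
accuracy 68.6%  sensitivity 24.4%  specificity 95.9%  AUC 0.743
IC_3    0.369
IC_4    0.288
IC_2    0.177
```

One component (here IC_3) carries the planted Aβ association
(point-biserial r ≈ −0.43 in this draw against a configured population
value of −0.52): lower "weighted GM volume" on that pattern accompanies
Aβ-positivity, the synthetic analogue of an AD-related atrophy pattern.
The same component tops the SHAP ranking, i.e. the classifier's decisions
rest chiefly on the component that actually separates the groups. The
brain-only model's moderate accuracy reflects the deliberately moderate
planted effect; adding the cognition and APOE blocks (`"ALL"` feature set)
raises performance substantially because those covariates are drawn from
strongly separated group distributions.

## Command line

```bash
sbmorph simulate --config cohort.yaml --out data/ --seed 0
sbmorph decompose --volumes data/volumes --k 7 --seed 0 --out sbm/
sbmorph fit --volumes data/volumes --table data/subjects.csv \
        --features ALL --folds 5 --mode nested --seed 0 --out fit/
sbmorph stats --table data/subjects.csv --loadings sbm/loadings.csv --out stats/
sbmorph run --config run.yaml --out report/ --seed 0
```

`run` executes the whole analysis (simulate-or-load → decompose → feature
ablation → diagnosis breakdown → SHAP → statistics) and writes a
machine-readable report: JSON plus CSV tables shaped like the cohort
summary, by-feature-set and by-diagnosis performance tables, the
component-by-clinical correlation table, and NIfTI z-maps of each
component (z ≥ 1 retained by default).

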