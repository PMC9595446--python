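# mldp

Automated, leakage-safe data preparation for small tabular clinical
cohorts. Given only a labeled training feature table, `mldp` searches —
with an evolutionary algorithm over a restriction-constrained pipeline
tree — for the ordered sequence of preparation operators (outlier removal,
feature selection, dimensionality reduction, over-/under-sampling,
purification) that maximizes a ROC-distance fitness measured strictly
inside the training data, then evaluates the prepared models with a
Monte-Carlo cross-validation harness.

## What is in the box

| module | purpose |
| --- | --- |
| `mldp.data_model` | `LabeledCohort` container + CSV/TSV ingestion (strict numeric parsing, label binarization) |
| `mldp.prep_ops` | the 8 preparation operators (IF, SFS, PCA, RO, RU, SMOTE, BSMOTE, TL) behind a uniform fit-on-train / transform-validation contract |
| `mldp.cohort_scores` | cohort diagnostics: outlier score (isolation forest) and borderline score (minority Tomek-link members) |
| `mldp.pipeline_space` | restriction table, pipeline validity, pipeline-tree enumeration and sampling |
| `mldp.mldp_search` | evolutionary optimizer (tournament selection, restriction-repairing crossover, structural + hyperparameter mutation, ROC-distance fitness, audit log) |
| `mldp.classifiers` | five fixed-default classifier schemes: RF, MG (bespoke diagonal-Gaussian), SVM, XGB-style gradient boosting, NN |
| `mldp.evaluation` | Monte-Carlo / dual-center experiment harness, confusion-matrix analytics, AUC, ANOVA, CI95, occurrence tallies |
| `mldp.synthetic_cohort` | seeded synthetic cohort generator with ground-truth bookkeeping (informative features, planted outliers, borderline overlap) |
| `mldp.cli` | `mldp` command-line entry point |

Sample-space steps (resampling, outlier/purification removals) only ever
touch training data; feature-space steps (SFS, PCA) are the only ones
replayed on validation data. Every search records the sample ids it
touched, and the harness aborts if a validation id ever appears there.

## CLI

```bash
# generate a synthetic cohort shaped like one of the built-in presets
mldp synth --preset glioma --seed 1 --out glioma.csv

# cohort characteristic scores (outlier / borderline), Table-style output
mldp scores --train glioma.csv --label label --positive positive --id-column sample_id

# pipeline-tree statistics under the default (or a YAML-configured) restriction table
mldp tree-stats

# search the best preparation pipeline on a training cohort
mldp search --train glioma.csv --label label --positive positive \
    --id-column sample_id --seed 7 --out run/

# full comparison experiment: no-DP vs searched-DP vs manual-DP arms
mldp run --train glioma.csv --label label --positive positive \
    --id-column sample_id --arms none,mldp,manual --schemes rf,mg,svm,xgb,nn \
    --folds 100 --seed 7 --out results/
# dual-center mode: train on center 1, validate once on center 2
mldp run --train center1.csv --validate center2.csv ... --out results/
```

A YAML config (`--config`) can override the restriction table and every
search parameter; each run directory receives a config snapshot so runs
are bit-for-bit reproducible from it.

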