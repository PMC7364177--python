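# mvpkit

Cross-validated multivariate (multivoxel) pattern analysis for neuroimaging
and tabular feature data: ROI-based and searchlight decoding, regression of
continuous scores, permutation inference with family-wise-error correction,
and multimodal data fusion — as a scriptable Python library with a thin
command-line interface.

## The problem

Univariate brain mapping asks, voxel by voxel, whether a signal differs
between conditions.  MVPA instead decodes the *joint pattern* across many
voxels: a classifier (or regression model) is trained on part of the sample
and must predict the class (patient vs. control) or score (e.g. reaction
time) of held-out samples.  Decoding accuracy above chance is evidence that
the pattern carries information, and the analysis doubles as a diagnostic
model.  Doing this correctly requires discipline that is easy to get wrong:
every preprocessing step must be fitted on training folds only, significance
must come from permutation (accuracies are not Gaussian), and voxel-wise
searchlight maps need correction over thousands of spheres.

## What the package computes

For samples x₁…x_n with two-class labels yᵢ ∈ {+1, −1} (or continuous
scores), split into K folds:

- **Cross-validated decoding.**  Per fold, the configured chain of
  transforms — Z-scoring Z=(x−m)/σ with training-fold statistics, PCA
  keeping the top components that explain ≥95 % of variance, F-score /
  weight-ranking / LASSO feature selection — is fitted on the training
  folds, then a model (linear C-SVC by default, c=1; also KNN k=11, logistic
  regression, Gaussian naive Bayes, LDA, decision tree, random forest with
  500 trees; e-SVR c=1, p=0.1 for regression) predicts the held-out fold.
  Performance is reported from the pooled confusion counts:
  Accuracy=(TP+TN)/(TP+FN+TN+FP), Sensitivity=TP/(TP+FN),
  Specificity=TN/(TN+FP), plus ROC/AUC from the pooled decision values, and
  the Pearson correlation r of predicted vs. true scores ("prediction
  precision") for regression.  Linear-model weights are mapped back to
  voxel space per fold and averaged.
- **Searchlight mapping.**  The same engine runs inside a sphere of a given
  radius around every in-mask voxel, producing a map of accuracies or
  prediction precisions.
- **Permutation inference.**  The null distribution retrains the entire
  pipeline N times on shuffled labels/scores and scores the predictions
  against the true labels; p = #{null ≥ observed}/N, reported as the bound
  P < 1/N when no null value reaches the observed statistic.  For
  searchlight maps, the per-permutation *maximum* over spheres forms a
  common null distribution, giving FWE-corrected p-values per center.
- **Data fusion.**  Feature-level: blocks of different feature types are
  concatenated (optionally Z-normalised per block) into one matrix.
  Decision-level: one model per block votes, each vote weighted by its own
  confidence (the signed decision value); regression fuses by averaging
  predicted values.

## Worked example

Everything below runs on synthetic data from the built-in fixture
generator — no download needed.

```python
import mvpkit
from mvpkit import synthetic

# 20 + 20 samples on an 8x8x8 grid; class +1 carries a 1.2-SD mean shift
# inside a 3x3x3 cube of voxels
spec = mvpkit.FixtureSpec(n_per_class=20, effect=1.2, seed=7, n_folds=10)
volumes, labels, folds, space = mvpkit.classification_dataset(spec)
data = synthetic.as_feature_matrix(volumes, space)

pipeline = mvpkit.Pipeline(model=mvpkit.make_model("svm", "classify"))
result = mvpkit.run_cv(data, labels, folds, pipeline, seed=7)
print("accuracy   ", result.aggregate["accuracy"])
print("sensitivity", result.aggregate["sensitivity"])
print("specificity", result.aggregate["specificity"])
fpr, tpr, auc = result.roc()
print("AUC        ", round(auc, 4))

perm = mvpkit.permutation_test(data, labels, folds, pipeline, 199, seed=7)
print("permutation:", perm.p)
```

Output:

```
accuracy    0.975
sensitivity 0.95
specificity 1.0
AUC         1.0
permutation: P < 0.00502513 (i.e., P < 1/199)
```

39 of the 40 held-out predictions are correct (one patient missed →
sensitivity 0.95), the pooled decision values separate the classes
perfectly (AUC 1.0), and none of 199 label-shuffled re-runs reaches the
observed accuracy, so the p-value is reported as the bound P < 1/199.

The same analysis is available from the shell via a YAML configuration:

```bash
mvpkit make-fixtures --out fixtures --n 20 --seed 7
mvpkit run analysis.yaml          # or: validate / searchlight / permtest / fuse
```

where `analysis.yaml` names the sample files, mask, label and fold columns,
preprocessing steps, model and outputs; `mvpkit run` writes metrics,
per-fold results, predictions, ROC points, weight maps and a fully resolved
copy of the configuration (every default materialised) so any run can be
replayed bit-identically.

## Scope notes

Inputs are NIfTI-1 volumes (.nii/.nii.gz) and header-free delimited text;
GIFTI/ANALYZE/.mat/spreadsheet dialects are not supported — convert
upstream.  Only two-way classification is implemented.  Upstream fMRI
preprocessing (realignment, normalisation, ReHo/fALFF/connectivity
computation) is out of scope; this package starts from per-sample feature
volumes or tables.
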