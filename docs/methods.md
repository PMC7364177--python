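# Methods

This note documents the statistical procedures, the conventions the package
commits to where the field leaves room, and what the synthetic fixtures do
and do not establish.

## Cross-validation engine

Samples are partitioned into K folds, either from a user-supplied fold
column or by seeded random assignment.  Random folds are even (sizes differ
by at most one) and, for classification, stratified: each class's per-fold
counts also differ by at most one, assigning each class's remainder to the
currently smallest folds (ties toward the lower fold index).  Every fold
serves as the test set exactly once; every preprocessing step and the model
are fitted on the training folds only.  This isolation is enforced by
construction and asserted by tests that perturb held-out samples and check
that fitted parameters (Z-score statistics, PCA loadings, selection sets,
model weights) are unchanged.

Classification metrics are computed twice: from the confusion counts pooled
over folds (the primary numbers — sample-weighted, well-defined for uneven
folds) and as the unweighted mean of per-fold accuracies (reported
alongside, since the two differ when folds are uneven).  A sensitivity or
specificity whose denominator is empty is reported as missing, never as 0.
The ROC curve and AUC are computed once from the pooled out-of-fold
decision values.  Regression performance ("prediction precision") is the
Pearson r between pooled out-of-fold predictions and true scores; it is
undefined (an error) for fewer than 3 pairs or zero variance.

## Feature preprocessing

**Z-transform.**  Z = (x − m)/σ.  In the column direction, m and σ are the
per-feature training-fold mean and *sample* standard deviation (ddof = 1,
the usual estimate from a training sample); the same parameters transform
the test fold.  In the row direction each sample is normalised with its own
row mean and *population* SD (ddof = 0 — the row is the entire population
of itself), identically for training and test.  Constant features (σ = 0)
map to 0 rather than NaN so they stay inert downstream.

**PCA.**  Thin SVD of the column-centered training matrix.  The default
rule keeps the smallest n components whose cumulative explained variance
reaches 95 % (so the top n reach it and the top n − 1 do not); an explicit
n is capped at min(n_train − 1, n_features), the rank of a centered matrix.
Test samples are projected as (x − train mean) · loadings.

**F-score ranking.**  For two classes, the classic equal-variance one-way
ANOVA F per feature.  Degenerate cases are ordered deliberately: zero
between- and within-class variance gives F = 0; nonzero separation with
zero within-class variance gives F = +inf, which sorts above every finite
score, with ties (including ties at +inf) broken toward the lower feature
index.  For continuous targets the analogue is the univariate regression
F = (n − 2) r²/(1 − r²), r being the feature–target correlation.

**Selection amounts.**  An integer is a count; a float in (0, 1] is a
fraction, mapped to floor(f · p) with a minimum of 1.  The selected set for
amount n is always a prefix of the set for n + 1 under the same tie-break.
When a configuration lists several amounts, each runs as an independent
analysis and the shared report annotates the Bonferroni-adjusted
α = 0.05/m; the report never shows only the best amount.

**LASSO.**  Objective (1/2N) Σ(yᵢ − ω₀ − xᵢᵀω)² + λ Σ|ωⱼ|, solved by
scikit-learn's coordinate descent.  λ is chosen by 10-fold cross-validation
*within the training fold*, minimising MSE over a grid of 100 values
log-spaced from the data-derived λ_max down to λ_max · 10⁻⁴; inner folds
are deterministic from the run seed and stratified for classification
labels.  Classification labels enter as numeric ±1 targets (the standard
embedded-selection device).  An empty selection at the chosen λ is an
error — silently keeping all features would misreport what the model used.
λ = 0 is handled as an ordinary least-squares fit (no sparsity).

## Models

Estimator internals are delegated to scikit-learn (the SVM path is libsvm,
the same optimiser family the original GUI tools wrap); this package owns
the defaults, seeding, decision-value conventions and weight extraction.
Defaults follow the printed GUI values: linear C-SVC with c = 1
(classification), linear e-SVR with c = 1, p = 0.1 (regression), g = 0.1,
d = 3, r = 0, nu = 0.5 where applicable, k = 11 neighbours, 500 trees.
Task coverage: all seven algorithms classify; SVM, KNN, tree and forest
also regress.

The cross-model decision value is sign-coherent and bounded where the model
is probabilistic: SVM reports the signed margin; LDA the signed
discriminant; logistic, naive Bayes, tree and forest report
2·(P(+1) − 0.5); KNN reports (votes₊ − votes₋)/k.  The predicted label is
the sign of the decision value with the single global tie rule: exactly 0
predicts +1, deterministically.  This uniform scale is what makes
decision-level fusion well-defined.

Conventions worth flagging:

- Gaussian likelihoods are assumed for naive Bayes — the natural choice for
  continuous voxel data.
- Logistic regression uses scikit-learn's L2-regularised fit (C = 1): the
  unregularised sigmoid fit is ill-posed in the n ≪ p regime this package
  targets.  Its `linear_weights` are the log-odds hyperplane, which is
  sign-consistent with (but not numerically equal to) the bounded
  probability-based decision value; for linear SVM and LDA the decision
  value equals w·x + b exactly.
- LDA uses the SVD solver, which is well-defined under singular
  within-class covariance, so no ridge fallback is needed.
- KNN distance ties at the k-th neighbour resolve to the backend's stable
  neighbour ordering (lower training index first).
- Forest resampling derives from the per-fold run seed, making every result
  bit-reproducible.

Weight maps: for linear models the per-fold weight vector is mapped back
through the preprocessing chain — scattered over the selected columns,
multiplied through the PCA loadings, divided by the column-Z σ (σ = 0 →
weight 0) — and written as NIfTI in the input geometry; the mean map is the
elementwise mean over folds.  Row-direction Z-scoring is a per-sample
transform that preserves the feature space, so weights pass through
unchanged.

## Searchlight

A sphere of radius r (voxel-lattice units by default; millimetres scale the
offsets by the voxel size) is the closed ball: all integer offsets d with
‖d‖² ≤ r², so radius 0, 1, 2 give 1, 7, 33 offsets.  Membership is clipped
to the volume and intersected with the mask; spheres with fewer than 2
voxels still run, and the sphere-size map lets users filter.  Centers
iterate in the canonical column order (ascending linear voxel index,
x fastest — the fixed, reproducible order all feature columns use).  Each
center's statistic is a pure function of its own sphere's columns, with any
model randomness derived from (seed, center index), so results are
independent of execution order.  Regression centers with degenerate
predictions (undefined correlation) carry NaN.

## Permutation inference

One globally shuffled label (or score) vector is drawn per iteration from a
generator that is a pure function of (master seed, iteration index); the
fold structure stays fixed, and the entire pipeline — including
training-fold feature selection and PCA — is refitted on the shuffled
labels.  The chance-level statistic scores the resulting out-of-fold
predictions against the *true* labels: the model is trained on random
labels and asked to predict the real test samples.  Scoring against the
shuffled labels instead would centre the null several points below 50 %
(the shuffled training and test compositions are anti-correlated under a
fixed total class count), which miscalibrates the reference; scoring
against the truth centres it at chance, as verified against scikit-learn's
independent permutation machinery.  p = #{null ≥ observed}/N (ties count,
so p = 1 when every null equals the observed value); a zero count is
reported as the bound P < 1/N, never as P = 0, since N limits the
resolution.

For searchlight maps, each permutation applies the *same* shuffled vector
to every sphere; the per-permutation maximum over spheres forms a common
null distribution, and each center's corrected p is its exceedance count
against those maxima — the max-statistic procedure, which controls
family-wise error and dominates the uncorrected p everywhere.  Per-sphere
uncorrected p-values are accumulated from the same permutations.
Within-group (stratified) shuffling is not offered.

## Data fusion

Feature-level concatenation joins blocks column-wise after an optional
per-block z-normalisation (per column, over all samples — a label-free
range alignment applied before the analysis, mirroring the usual practice
of normalising each modality before building the fused matrix; it uses no
class information, but strictly speaking its scale factors see all samples).
Normalisation defaults to off, since feature types on comparable scales
need none.  The fused space is tabular (geometry is lost), with a
block → column-range index retained so linear weights can be reported per
block.

Decision-level voting trains one model per block on identical folds and
sums the models' signed decision values per test sample; since each value's
magnitude is the model's confidence, this is confidence-weighted majority
voting, and the fused label is the sign (0 → +1, the global tie rule).
Regression fuses by the unweighted mean of predicted values — confidence is
not well-defined for a regression output, whose decision value *is* the
prediction.  Both strategies reduce exactly to the plain pipeline for a
single block, and the vote is invariant to block order.

## Synthetic fixtures

The generator emulates the structure the analyses need and nothing more:
per-sample i.i.d. Gaussian voxel noise on a small grid (default 8×8×8,
n = 40, matching a typical small two-group study), with a box-shaped signal
region — a class mean shift of `effect` noise-SDs (classification) or a
voxel value proportional to the sample's score, slope `regression_slope`
with scores Uniform(400, 700), emulating reaction times in ms
(regression).  Folds are written stratified; identical spec + seed gives
byte-identical files.  Optional isotropic Gaussian smoothing adds spatial
autocorrelation (off by default).

What it deliberately lacks: hemodynamics, physiological and motion noise,
spatially varying smoothness, class covariance structure.  Passing tests
therefore establish the *engine's* correctness and calibration — leakage
safety, chance-level behaviour, geometric localisation — not performance
claims about real fMRI data.

Default scales were chosen to keep the full suite at desk scale: grid
8×8×8 (512 voxels), 20 samples per class, K = 10 folds; calibration tests
use 200 seeded datasets with N = 99 permutations, and trend tests average
20–50 seeds.  The regression trend demonstration (top-10 % F-score
selection beating all-voxels selection when ~95 % of voxels are irrelevant)
uses a slope at which the selected-voxel analysis reaches a prediction
precision of ~0.6–0.8 — an informative-signal regime; at much weaker
signal the comparison drowns in seed noise.

## Known limitations

- Two-way classification only; no multi-class.
- No nested model selection beyond the LASSO λ rule; reported accuracies
  for several selection amounts are multiple analyses and flagged with the
  Bonferroni-adjusted α.
- No spatial inference beyond voxel-wise FWE (no cluster-mass or TFCE).
- The searchlight loop is single-process; per-center independence makes it
  trivially parallelisable, but the contract is bit-identical output in any
  execution order.
- Probability calibration (Platt scaling) is not exposed for SVM; its
  decision value is the uncalibrated margin.
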