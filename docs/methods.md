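# Methods

## Model and procedure

`costaware` treats budget-constrained risk modelling as three separable
problems: *credit assignment* (how much does each feature drive the trained
model's predictions), *selection* (which affordable subset keeps the most
credit), and *refitting* (rebuild the predictor so it uses only what was
bought).

**Credit assignment.** Attributions are Shapley values of the model output
with *interventional* masking: the value of a feature coalition S at input
x is the mean model output over a background sample whose S-coordinates are
overwritten by x. Interventional (rather than conditional/observational)
masking was chosen because it matches the mean-imputation used in
preprocessing and keeps the linear closed form exact; the background set is
drawn from the training split and is exposed as a parameter. Three routes:

- exact subset-weighted sum, 2^M coalition evaluations, refused above
  M = 12;
- Monte-Carlo permutation sampling, unbiased, SE ∝ 1/√(n_permutations);
  default 200 permutations per sample when called directly;
- closed form φ_i = w_i(x_i − mean_i) for linear scores.

Linear models are scored on the log-odds (decision-function) scale so the
closed form is exact; sigmoid is monotone, so ranking metrics (AUROC,
recall at precision) are unaffected.

Global importance is mean |φ_ij| over samples by default; the sum variant
differs by the factor n and selects identical subsets. Inside the pipeline,
attributions are computed on the **validation split** (train would reward
overfit features; test must stay untouched), capped at 200 evaluation
samples and 50 background rows, and the pipeline's sampling default is 30
permutations per sample — a runtime compromise that is noisy per sample but
stable after averaging over the evaluation set; raise
`AttributionConfig.n_permutations` for per-sample use.

**Selection.** The knapsack is solved by dynamic programming after scaling
costs to integers at a resolution of 1e-3 × the smallest nonzero cost
(coarsened only if the table would exceed 2×10^6 cells). The solution is
exactly optimal for the scaled instance and deterministic. Tie-breaks are
fixed: maximum importance, then minimum realized cost, then earliest
cost-file order (the DP backtrack prefers excluding later items on exact
ties, which realizes the file-order rule). Features with zero importance
are dropped before the DP; they cannot raise the objective. Grouped costs
run the same DP over (φ_g, c_g) and expand the winning groups to features.
Greedy scans features by decreasing φ_i/c_i and by default *skips* an
unaffordable feature and continues (maximizing budget use); a
stop-at-first-failure flag gives the stricter variant, since the verbal
description "until no more can be added" admits both readings.

**Pseudocosts.** Zero-cost features (dispatch fields, free exam findings)
make φ/c undefined. Each receives ε = g / (2(z+1)), where g is the minimum
gap between distinct nonzero costs and z the count of zero-cost features,
so Σε < g strictly and no feasible set at any budget separating two nonzero
costs changes. With fewer than two distinct nonzero costs the gap condition
is vacuous and g falls back to the minimum nonzero cost. Pseudocosts are
used for ranking and feasibility only; reported realized costs always use
original costs.

**Refitting.** The restricted model is a clone of the base estimator —
same class, same hyperparameters — fit on the selected columns of the
train split. The no-retrain variant instead keeps the full model and
replaces unselected features with train-split means at prediction time:
one training instead of two, typically worse, and the gap grows with
feature correlation (a refit re-weights correlated survivors; masking
cannot). Recursive elimination refits and re-attributes after every
removal, so it can track feature dependence, at the price of up to M fits.
An empty selection (k below every cost) predicts the train-split base rate,
a constant score with AUROC 0.5 — the natural k → 0 limit.

## Preprocessing

Continuous features are standardized and missing values mean-imputed using
train-split statistics only; a seeded shuffle makes the 64/16/20
train/validation/test split. Categoricals are one-hot encoded (missing as
its own level); all indicators of one categorical share a group — you
cannot acquire half a categorical — and inherit its cost. Constant columns
standardize to zeros with a warning. The base-model defaults mirror common
clinical-tabular practice: gradient-boosted trees at learning rate 0.01, up
to 1000 trees, early stopping after 100 stagnant rounds; L2 logistic
regression. Hyperparameter search is the caller's concern and must happen
before cost-aware training — the retraining contract requires frozen
hyperparameters. The full-feature fit uses the train split alone (rather
than train+validation) so the validation split remains untouched for
attribution.

## Evaluation utilities

AUROC is the rank statistic (ties ½). Recall at a precision target is the
maximum recall over thresholds attaining that precision, 0 if unattainable;
false:true alert ratios convert to precision targets by the caller (4:1 →
0.2). Deployment extrapolation is recall × national positive count,
rounded half away from zero. Curve alignment interpolates each replicate's
(cost, AUROC) points onto a common 100-point linear cost grid by
previous-value steps — a conservative estimate: a 5-minute query returns
the 4-minute model when no 5-minute model exists. Grid cells below a
replicate's cheapest model are masked and excluded from means (a flag
extends the cheapest value downward instead). Curve comparison is a
two-sided paired t-test, paired by split replicate, on per-replicate mean
AUROC; zero-variance differences are flagged degenerate (identical sets:
t = 0, p = 1; constant shift: t = ±∞, p = 0) rather than erroring.

The bisection tuning harness treats a cost-penalized learner as an opaque
map λ → (cost, performance), monotone non-increasing in λ. Published
descriptions of this procedure give garbled update formulas; this package
implements textbook bisection with explicit (lo, hi) bound updates,
starting from λ₀ with bounds (0, 10^6) and at most T = 128 trainings,
stopping early when a feasible model's cost is within a relative tolerance
(default 1%) of the budget or the bracket collapses. It returns the
best-performing feasible model seen and the training count — the
comparison point for the two-training direct path.

## Synthetic cohorts

The generator draws y ~ Bernoulli(prevalence) and features x_j ~
Normal(d_j·y, 1), independent by default. This stated world has closed-form
answers: the Bayes score on subset S is d_S·x_S and its AUROC is
Φ(‖d_S‖₂/√2), so the budget-optimal subset is computable by enumeration
(`true_best_subset`) and end-to-end recovery is checkable without real
data. Templates emulate three cohort structures — trauma-like (45 features,
minutes, 6 zero-cost dispatch/procedure fields, prevalence 0.06), ICU-like
(43 unit-cost features, prevalence 0.09), outpatient-like (27 acquisition
groups → 35 features → 118 one-hot columns, dollars); prevalences are this
package's choice of rare-outcome regimes. Categoricals are quantile-binned
latent Gaussians; an equicorrelation mode (shared Gaussian factor) exists
for stress tests and carries no closed-form claims.

What a green test does *not* establish: the generator has no missingness
mechanism, no temporal structure, no realistic marginals, and (by default)
no feature dependence — real-cohort performance claims cannot be read off
these tests. The recovery test world (M = 8, distinct effects 0.1–1.2,
costs {1, 4}, budget 3, n = 5000) was fixed a priori so that the knapsack
optimum under Σφ coincides with the Bayes optimum under ‖d‖₂; the two
objectives can genuinely disagree (e.g. effects (3, 2, 2), costs (2, 1, 1),
budget 2: Bayes prefers the single strong feature, Σ|d| the cheap pair),
which is a known limitation of additive-importance selection, not a bug.
The strategy-ordering test uses equicorrelation 0.3 because the
retrain-vs-mask gap requires feature dependence to exist at all.

## Numerical choices and limitations

- DP resolution 1e-3 × min nonzero cost; tests that compare against the
  brute-force oracle use costs that are exact multiples of the resolution
  so scaling is lossless.
- One pipeline seed deterministically derives the split, model and
  attribution seeds (via `numpy.random.SeedSequence`).
- Budget sweeps reuse the cached full model and importances: 1 + B fits
  for B budgets.
- Additive costs and additive importances are assumed throughout; feature
  interactions are credited by Shapley averaging but the selector ignores
  them (no submodular or interaction-aware optimization).
- Per-sample adaptive acquisition (different features for different
  patients) is out of scope; every model here measures one fixed feature
  set.
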