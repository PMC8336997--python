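# Methods

## Model

For outcome y (n samples) and features X (n × p), each base learner k is a
penalized GLM E[y] = h⁻¹(β₀ + Xβ) with elastic-net penalty

    ρ(λ, α; β) = λ Σⱼ wⱼ ( (1−α)/2 βⱼ² + α |βⱼ| ),

intercept unpenalized, optional per-coefficient multipliers wⱼ (wⱼ = ∞
excludes a coefficient) and optional box constraints on each βⱼ. Canonical
links are used throughout (identity/logit/log), so the score is X'(y − μ)
and a single solver core serves all three families.

The stacked elastic net fits base learners on an equally spaced α grid
(m = 21 by default: {0, 0.05, …, 1}, which contains exact ridge and lasso
endpoints and the ridge-like 0.05 / lasso-like 0.95 comparators as grid
members), tunes each λₖ on its own exponentially decreasing path by K-fold
cross-validation (K = 10), stores the out-of-fold linear predictors at λₖ*
in Ĥ (n × m), and fits the meta learner: a lasso of y on Ĥ with weights
constrained to [0, 1], intercept unpenalized, λ tuned on the *same* folds.
For non-gaussian outcomes the meta regression uses the family's own
likelihood conditional on Ĥ (the natural reading of a family-specific
meta loss). Refitting base and meta on all folds and pooling gives one
intercept and one slope per feature; the pooling identity
(predictions from pooled coefficients = ω-weighted base predictions) is
exact by linearity and is asserted in the tests to 1e-10.

The tuned elastic net (cross-validation selection) is the special case
ω₀ = 0 with a one-hot ω; it is exposed as `select_tuned` and used as the
main comparator. Ridge/lasso/ridge-like/lasso-like comparators are read
off the grid.

## Solver

Coordinate descent on standardized features (column mean 0, sd 1 with
denominator n; coefficients back-transformed), numba-compiled, with:

* glmnet-style convergence metric maxⱼ dⱼ·Δβⱼ² (dⱼ = column mean square);
  path/CV fits stop at 1e-7, single fits at 1e-14 so that the
  coordinate-wise stationarity residual is ≤ 1e-7;
* warm starts along the λ path and sequential strong rules: each λ is
  solved on the screening set {|gⱼ| ≥ α(2λ − λ_prev)wⱼ} ∪ {βⱼ ≠ 0}, then
  every excluded coordinate is checked for optimality and violators are
  added (exactness does not depend on the screen);
* box constraints handled by clipping the closed-form coordinate update
  (valid because the one-dimensional subproblem is convex);
* binomial/poisson via iteratively reweighted least squares around the
  current linear predictor (μ clamped to [1e-5, 1−1e-5] for binomial,
  η to ±30 for poisson), sharing the weighted gaussian core;
* an exact SVD path for the pure-ridge gaussian special case (α = 0,
  uniform weights, no bounds).

λ_max is the smallest λ with all slopes zero, computed from the
intercept-only score; α is floored at 0.001 in that formula because pure
ridge has no finite λ_max. Paths have 100 values down to ratio 0.01 of
λ_max when p ≥ n and 1e-4 otherwise. λ* always minimizes the mean CV
deviance, ties broken toward the larger λ (more regularization); the tuned
α breaks ties toward the smaller α.

Zero-variance columns are frozen at zero. Degenerate fits (λ_max = 0 under
a null signal) fall back to a tiny default path with a warning.

### Outcome scaling for the gaussian base learners

`enet_path(..., scale_outcome=True)` divides a gaussian outcome by its
sample sd before solving and rescales the fit; supplied λ values are
interpreted on the original outcome scale. This makes the ridge/lasso
balance of the penalty invariant to the outcome's units and extends the
effective ridge path (the α = 0 CV optimum otherwise pins at the path
boundary because λ_max/α_floor sets a very high starting penalty). It is
the convention of the widely used R implementation of the elastic net, and
the base learners adopt it by default. The meta learner and the post-hoc
selection step are pure lasso (α = 1), for which outcome scaling provably
cannot change the solution path, so they operate unscaled — this also
keeps the [0, 1] constraints on the meta weights on the original scale.
Direct calls to `fit_penalized_glm` default to the unscaled objective
written above.

## Post-hoc selection (decoupling shrinkage and selection)

The pooled linear predictor η̂* = β*₀ + Xβ* is approximated by a gaussian
adaptive lasso of η̂* on X with multipliers wⱼ = 1/|β*ⱼ| (wⱼ = ∞ when
β*ⱼ = 0, so the selected support is always contained in the pooled
support). The multipliers are renormalized to mean 1 over their finite
entries so λ is on a familiar scale; renormalization rescales the whole
path and cannot reorder supports. The constant β*₀ is absorbed exactly by
the unpenalized intercept γ₀. λ is chosen either by K-fold CV of the
η̂*-prediction MSE on the model's own folds (coherent with the stacked
fit), or as the densest path element whose non-zero count stays at or
below a requested cap — ties toward the larger λ — so the cap is a hard
guarantee. `dss_cv_deviance` refits the approximation fold-wise and scores
the held-out outcome, so the cost of sparsification is measurable against
the dense model.

## Synthetic data

*Prediction scenarios.* Latent signals z₁, z₂, z₃ ~ N(0,1) i.i.d.;
y = z₁ + z₂ + z₃ (Var y = 3). Features are xⱼ = √π z_l + √(1−π) εⱼ with
private noise εⱼ ~ N(0,1), so Var xⱼ = π + (1−π) = 1 exactly. (Printed
sources sometimes typeset the combination weights without the radicals;
only the square-root form satisfies the unit-variance identity, which is
what the generator enforces and the tests check.) Scenario 1: features 1
and p tied to z₁/z₂ with π = 0.9, rest pure noise. Scenario 2: first half
tied to z₁, second half to z₂, all π = 0.1. Scenario 3: first and last 5%
tied with π = 0.5. Defaults n = 10 000, p = 500; 100 samples train (with
internal 10-fold CV), 9 900 test.

*Estimation scenarios.* X ~ MVN(0, Σ) with Σⱼⱼ = 1, Σⱼₖ = 0.1, generated
exactly as √ρ·g + √(1−ρ)·E with a shared g ~ N(0,1); q ∈ {5, 50, 20}
coefficients equal 1 (placed on the first q features — immaterial under
the exchangeable covariance), the rest 0; residual sd is half the sample
sd of Xβ (Var(Xβ) = q + q(q−1)ρ, giving a closed-form moment check).
n = 100, p = 500, no test split.

What the generators do **not** emulate: real omics features are
non-gaussian, heteroscedastic, block-correlated and measured with
platform-specific noise; effects are not all equal. Passing benchmarks
therefore demonstrates correct method behavior under the stated sampling
models, not performance on any particular biological dataset — for that,
the nested-CV harness accepts user matrices.

## Benchmarks and their summaries

Every replication r uses seed (base + r); all methods within a replication
share (X, y, folds), so comparisons are paired (asserted by data hash).
Summaries are recomputed from persisted per-replication rows.

* Prediction: per-method test MSE; the "best-approach fraction" counts
  replications where the stacked model's MSE is strictly the lowest among
  {ridge, lasso, tune, stack} (the four box-plot methods); two-sided
  Wilcoxon signed-rank p-values (zeros dropped; exact up to 25 informative
  pairs, tie-corrected normal beyond) are reported per comparison, with
  any Bonferroni adjustment left to the caller.
* Estimation: MAE and MSE of β̂ against β separately over truly-zero and
  truly-nonzero coordinates; the headline quantity is the median over
  replications of the per-replication percentage decrease
  100·(err_tune − err_stack)/err_tune on non-zero coordinates (the
  decrease of the medians is also reported as an alternative reading).
* Selection: stacked + capped post-hoc selection vs the lasso and the
  lasso-like elastic net constrained to the largest path λ with at most
  `cap` non-zeros; TP, FP and precision TP/(TP+FP) per replication
  (precision 0 with a log message when nothing is selected); means over
  replications, reported per scenario (and recomputable pooled across
  scenarios from the rows).
* Repeated nested CV: outer folds estimate the generalization deviance,
  inner folds tune; the method name "intercept" scores the null model,
  whose deviance on balanced binomial data is 2·log 2 in closed form — the
  harness's self-check.

## Problem sizes

The shipped acceptance runs and the corresponding tests use 50
replications per scenario (the study conditions otherwise unchanged:
n = 10 000/100, p = 500, m = 21, K = 10, 100-value λ paths). At 50
replications the binomial standard error of a best-approach fraction near
80% is ≈ 6 points, and the medians of the estimation decreases are stable
to a few points; the runners accept any `reps` for tighter Monte-Carlo
error.

## Known limitations

* Families are gaussian/binomial/poisson with canonical links only.
* The solver is dense; sparse inputs are densified on load.
* CV curves pool per-sample deviances (equivalent to fold-averaging for
  equal fold sizes, marginally different otherwise).
* The one-standard-error λ rule is deliberately not offered: with the
  minimum rule the stacked model reproduces the reference behavior, and
  the 1-SE variant degraded it markedly in exploratory runs.
* Post-hoc selection approximates the dense predictor; with a very sparse
  pooled model the path may not reach a requested cap (warned, densest
  available element returned).
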