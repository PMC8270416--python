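# Methods

## Model and estimator

Tract-profile features are organized as an S x P matrix **X** whose columns
partition into G = B x M groups, one per (bundle, metric) pair, each of
p_ℓ = N node columns ordered along the bundle.  For a phenotype y the
package solves

    β̂ = argmin_β  L(β) + (1 − α) λ Σ_ℓ w_ℓ ‖β^(ℓ)‖₂ + α λ ‖β‖₁

with L the squared-error loss ½‖y − b₀ − Xβ‖² (continuous y) or the
summed logistic cross-entropy (binary y ∈ {0, 1}).  Neither loss carries a
1/n factor, so λ scales with the sample size; all search ranges are
therefore expressed as a fraction of λ_max (below), which makes them
scale-free.  The group weights default to w_ℓ = √p_ℓ, the standard SGL
convention under which equal-sized groups are weight-neutral; they are
configurable.  The intercept is never penalized: for squared error it is
absorbed by centering X and y (and reconstructed as b₀ = ȳ − x̄ᵀβ̂), for
the logistic loss it is an explicit unpenalized coordinate.

The logistic model is p(y = 1) = 1 / (1 + exp(−(b₀ + xᵀβ̂))), so positive
coefficients increase class-1 probability; class labels use the p ≥ 0.5
rule, with the tie going to class 1.

## Solver

Proximal gradient descent with FISTA momentum, safeguarded to be monotone:
each iteration takes the momentum step with a backtracking line search
(halving from 1/L̂, with L̂ a 50-step power-iteration estimate of ‖X‖₂²,
times ¼ for the logistic Hessian bound); if the momentum step would
increase the objective the iteration falls back to a plain proximal step
and restarts the momentum sequence.  The proximal operator of the mixed
penalty is exact and closed-form: elementwise soft-thresholding at
step·αλ followed by per-group norm shrinkage at step·(1−α)λ·w_ℓ, with the
whole group set to zero when its soft-thresholded norm falls below the
group threshold.

Termination is by the max-norm of the minimal KKT subgradient (including
intercept stationarity), checked every 10 iterations; defaults are
tol = 1e−7 and max_iter = 5000 for standalone fits, relaxed to 1e−6 /
2000 inside cross-validation loops where thousands of fits run (the tuned
hyperparameters are insensitive to the last decades of the residual).
Non-convergence is flagged on the returned model and warned about, never
silent.  Fits are exactly deterministic for fixed inputs: the only
randomness in the package flows from explicit seeds.

λ_max — the smallest λ whose solution is exactly zero — is computed from
the subgradient condition at β = 0 with the intercept at its unpenalized
optimum: for each group, the root in λ of
‖soft(g^(ℓ), αλ)‖₂ = (1 − α) λ w_ℓ (a monotone scalar equation, solved by
bisection to 1e−14), maximized over groups; the α = 1 and α = 0 endpoints
have the usual closed forms.

## PCR-SGL

Each group block of the (z-scored) training matrix is reduced by compact
SVD, X^(ℓ) = U Σ Vᵀ, keeping singular values above 1e−12 times the group's
largest (numerical rank).  Axis signs are fixed by making each axis's
largest-magnitude loading positive, so refits on identical data are
bit-identical.  The SGL is then fitted on the score matrix Z (group ℓ
contributing r_ℓ columns, weight √r_ℓ — the transformed group dimension),
and coefficients back-project exactly per group: β̂^(ℓ) = V^(ℓ) θ̂^(ℓ).
Score-space and feature-space predictions are algebraically identical
because Z = XV blockwise.  Scores are deliberately not re-standardized
before the score-space fit: the variance ordering inherited from Σ is the
parsimony argument for the PC projection, and erasing it would make the
projection pointless; a caller can standardize externally if desired.

## Preprocessing

Missing node values are imputed per subject and per group only — linear
interpolation on node index for interior gaps; for exterior gaps either
linear extrapolation from the two nearest observed nodes (the default) or
constant nearest-value fill.  Imputation never crosses a (bundle, metric)
boundary and never uses another subject's values, so it cannot leak
information across CV folds.  A subject x group profile that is entirely
missing is an error, as is a missing fraction above the policy cap
(default 0.5).

Features are z-scored with the population (divide-by-n) variance
convention; statistics are fitted on training rows only.  Zero-variance
columns get scale 1 — they become all-zero after centering instead of
killing the fit, which matters for degenerate synthetic inputs.  A no-op
harmonization hook sits between imputation and scaling for users who need
to insert a site-effect correction; the package itself assumes single-site
or pre-harmonized input.

Targets may be fitted on a log scale (requires strictly positive values;
violations are reported with the offending subject IDs).  Predictions are
always returned, and all metrics computed, on the original scale.

## Hyperparameter search and nested cross-validation

Generalization is estimated with nested CV: k₀ outer folds (default 10,
configurable to 5), and within each outer training set k₁ = 3 inner folds
that score (α, λ/λ_max) candidates by mean held-out R² (continuous) or
accuracy (binary).  Classification folds are stratified.  λ is always
parametrized as ratio x λ_max of the training split at hand.  Two search
modes exist: an exhaustive, deterministic grid (default grids
α ∈ {0, 0.25, 0.5, 0.75, 1}, ratio log-spaced on [1e−3, 1]); and a seeded
sequential model-based optimizer — Gaussian-process surrogate (Matérn 5/2
plus white noise) with expected-improvement acquisition over a 256-point
random pool, a quarter of the budget spent on random initialization.  One
master seed fans out deterministically (via SeedSequence paths) to fold
shuffling, the optimizer, bootstrap resampling, and data generation, so a
whole run is reproducible byte-for-byte from its config.

Per outer fold the pipeline refits the scaler (and PC basis, where
applicable) on the outer training set, tunes on the inner folds, refits on
the full outer training set — optionally as a bagged ensemble (default
m = 20 bootstrap resamples) whose constituents share the tuned (α, λ) and
whose coefficients, hyperparameters and predictions are arithmetic means;
regression predictions are averaged on the transformed scale and
inverse-transformed once — and predicts the held-out fold.  Every subject
receives exactly one out-of-fold prediction; pooled metrics (R², MAE,
median absolute error; accuracy, ROC AUC) are computed once from those,
with per-fold distributions also reported.  Baseline estimators (pure
lasso, elastic net via scikit-learn, bundle-mean lasso, global PCR-lasso)
run under the identical fold plan so comparisons are paired.

The randomization test repeats the entire nested-CV pipeline on copies of
the data with permuted targets (features fixed) and reports the null
distribution of the headline metric and the observed metric's empirical
quantile.  A pipeline that beats chance on shuffled targets has a leak;
the test suite additionally asserts exact invariance of every train-fitted
parameter under gross perturbation of held-out rows.

## Tuning for support recovery

Predictive CV tuning and support identification pull in different
directions: the λ minimizing prediction error is known not to be
model-selection consistent, and CV-tuned SGL fits typically include a few
spurious groups with small coefficients (recall 1, imperfect precision).
When the scientific question is "which bundles carry signal?" the package
offers `tune_by_ebic`, which selects (α, λ/λ_max) by the extended Bayesian
information criterion, EBIC = n log(RSS/n) + df (log n + 2γ log P)
(deviance replacing the first term for logistic fits), with df the nonzero
coefficient count and γ = 1 the conservative default for P ≫ n.  EBIC is
consistent for support selection in this regime; on the generator's
standard support-recovery conditions it recovers the exact active-group
set in ~19/20 seeds where CV tuning recovers it in none.  Prediction
metrics should still be quoted from CV-tuned fits.

## Synthetic data generator

The generator emulates the structure that makes tract profiles
statistically distinctive, with defaults fixed at realistic study
conditions: profiles of N = 100 nodes for 18 bundles x 2 metrics and a few
dozen subjects; per subject x group a profile equal to a group-level latent
(sd 1) plus stationary AR(1) node noise with lag-1 autocorrelation ρ = 0.5,
so nearby nodes co-vary; ground-truth β zero outside n_active randomly
chosen groups and, inside each, a contiguous run covering a configurable
fraction of nodes (default 0.5) with a half-sine amplitude profile and
random sign — mirroring the localized bundle segments seen in real
coefficient profiles (a scattered placement mode exists).  The continuous
target is Xβ rescaled so that sd(Xβ)/noise_sd equals the requested effect
size (default 2), plus Gaussian noise; with a log target transform the
observed target is exp of that, forcing the pipeline to re-transform.
Binary targets are Bernoulli draws of the logistic of the linear predictor,
whose sd is set to the effect size (Bernoulli noise being intrinsic).  When
noise_sd = 0 the ratio is undefined and the linear predictor is scaled to
unit sd.  Missingness injection masks a fraction of nodes per profile under
interior / exterior / random patterns, never masking an entire profile.
Everything is deterministic given the spec seed.

What the generator does *not* emulate: FA's [0, 1] range and metric-specific
units (features are Gaussian), cross-bundle covariance (groups are
independent, which favors group-selection methods), site/scanner batch
effects, and realistic missingness mechanisms (masking is random, not
tract-segmentation-failure shaped).  Passing tests therefore demonstrate
correctness of the estimators and the honesty of the evaluation machinery,
not clinical effect sizes; headline numbers from real cohort studies are
not reproducible from synthetic data and are not claimed.

## Numerical choices and degenerate inputs

- Prox and penalty are exact for λ = 0 (identity / zero).
- Zero-variance features: scale 1, column becomes all-zero (never an
  error).
- Single-class bootstrap resamples in classification bagging are redrawn
  (up to 100 times, then an error).
- ROC AUC on single-class held-out data is reported as missing with a
  warning rather than raising.
- Degenerate tuning (every candidate failing) returns the most
  regularized candidate with a warning.
- Group-lasso block updates, rank decisions, and axis signs all carry
  explicit deterministic tie-breaks, so repeated runs agree exactly.

## Problem sizes used in the shipped checks

The test suite and acceptance script run on synthetic problems sized so
the full battery completes in a few minutes on one CPU: oracle batteries
at n ≤ 50, P ≤ 60; support recovery at S = 200 with 20 groups of 10 nodes
over 10–20 seeds; nested-CV demonstrations at S = 48–80 with 40–100
features and compact tuning grids.  These sizes are the package's chosen
demonstration conditions; the estimators themselves are routinely usable
at the full 18 x 100 x M scale (the dimension tests exercise assembly up
to P = 14,400).

## Known limitations

- Non-overlapping groups only; fused/overlapping penalties are out of
  scope.
- The elastic-net baseline is a scikit-learn delegate, so its λ
  parametrization matches only up to the documented rescaling.
- EBIC tuning is implemented for support analyses; a full model-selection
  study (e.g. stability selection) is not included.
- The SMBO tuner is a compact GP implementation intended for the small
  2-D search space, not a general black-box optimizer.
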