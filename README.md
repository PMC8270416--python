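# tractsgl

Sparse group lasso (SGL) analysis of diffusion-MRI tract profiles.

Tractometry samples tissue properties (fractional anisotropy, mean
diffusivity, ...) at N ordered nodes along each of B white-matter bundles,
giving every subject a feature vector of P = B x N x M values whose columns
fall into natural groups — one group per (bundle, metric) pair.  Typical
studies have far more features than subjects (e.g. 3,600 features for a few
dozen subjects), so predicting a phenotype y (age, diagnosis) from the
profile matrix **X** is ill-posed without regularization.  `tractsgl` is
for researchers who want to both *predict* a phenotype from tract profiles
and *localize* which bundles and which segments along them carry the
signal.

## The model

The package fits the linear model y = Xβ + ε by solving

    β̂ = argmin_β  L(β) + (1 − α) λ Σ_ℓ √p_ℓ ‖β^(ℓ)‖₂ + α λ ‖β‖₁

where β^(ℓ) is the coefficient block of group ℓ (p_ℓ = N nodes), L is the
squared-error loss ½‖y − b₀ − Xβ‖² for continuous targets or the logistic
cross-entropy for binary ones, α ∈ [0, 1] mixes whole-group selection
(α = 0, the group lasso) with individual-feature selection (α = 1, the
lasso), and λ ≥ 0 sets the overall strength.  The solver is proximal
gradient descent (monotone FISTA with backtracking) around the exact
closed-form proximal operator of the mixed penalty, terminating on the KKT
subgradient residual.

Around the core estimator the package provides:

- **AFQ-Browser CSV I/O** (`nodes.csv` / `subjects.csv`), missing-node
  imputation that never crosses bundle boundaries, and train-only
  z-scoring;
- **PCR-SGL**: each group is first projected onto its own principal
  components (compact SVD), the SGL is fitted in score space, and the
  coefficients are back-projected exactly (β̂ = Vθ̂);
- **bagging** (default m = 20 bootstrap constituents, averaged
  coefficients, hyperparameters and predictions);
- **log target transform** for age-like targets;
- **nested cross-validation** (k₀ outer folds for honest evaluation, k₁ = 3
  inner folds for hyperparameter search by exhaustive grid or GP-based
  sequential optimization), a **randomization (shuffled-target) test**, and
  baseline estimators (lasso, elastic net, bundle-mean lasso, global
  PCR-lasso) that run under the identical fold plan for paired comparison;
- a **synthetic tract-profile generator** with known group-sparse ground
  truth, so the entire pipeline is testable without any imaging data.

## Worked example

Simulate an 80-subject dataset (5 bundles x 2 metrics x 10 nodes, 2 active
groups carrying a strong continuous signal), then evaluate SGL with nested
cross-validation:

```bash
tractsgl simulate --out demo --subjects 80 --bundles 5 --metrics 2 \
    --nodes 10 --n-active 2 --active-fraction 1.0 --effect-size 3 --seed 42
echo '{"alpha_grid":[0.0,0.5,1.0],"ratio_grid":[0.02,0.1,0.3]}' > demo/cv.json
tractsgl cv --nodes demo/nodes.csv --subjects demo/subjects.csv \
    --target target --estimator sgl --k0 3 --k1 3 --seed 0 \
    --config demo/cv.json --out demo/cv
```

The `cv` command prints the pooled out-of-fold metrics:

```
{"r2": 0.8387226679091476, "mae": 1.0034075053424942, "median_ae": 0.9049786545658624}
```

R² = 0.84 means the tuned model explains 84% of the held-out target
variance; every subject's prediction comes from a model that never saw that
subject.  `demo/cv/metrics.json` additionally reports per-fold metrics and
the mean selected hyperparameters — here `mean_alpha = 0.0`: the tuner
correctly recognized a whole-group signal and chose the pure group-lasso
penalty.  `demo/cv/coefficients_mean.csv` maps the fold-averaged β̂ back to
(tractID, metric, nodeID) coordinates and
`demo/cv/coefficients_mean_group_summary.csv` gives the mean |β̂| per
bundle-metric group, which is how one reads off the anatomically selected
bundles.

A shuffled-target control (`tractsgl permtest ... --n-shuffles 20`)
re-runs the identical pipeline on permuted targets and should — and does —
perform at chance, which guards against information leakage.

The same workflow runs on real AFQ output unchanged: point `--nodes` /
`--subjects` at the CSV files produced by mAFQ/pyAFQ (optionally with
`--transform log` for age targets, `--estimator pcr_sgl`, `--bag-m 20`).

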