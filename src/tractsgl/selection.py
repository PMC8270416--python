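"""Nested cross-validation, hyperparameter search, metrics, permutation test.

The outer k0 folds estimate generalization; within each outer training set,
k1 inner folds score (alpha, lambda) candidates.  Every train-only
statistic — imputation (per-subject, inherently leakage-free), the scaler,
any PC basis, and the tuned hyperparameters — is a function of training rows
only.  lambda is always searched as a fraction of lambda_max computed on the
training split at hand, which keeps search ranges scale-free.

Estimators:

==================  ==========================================  =========
name                features                                    alpha
==================  ==========================================  =========
sgl                 z-scored profiles, bundle-metric groups     tuned
pcr_sgl             group-wise PC scores, groups preserved      tuned
lasso               z-scored profiles                           fixed 1
bundle_mean_lasso   per-group mean profile values               fixed 1
pcr_lasso           global PC scores                            fixed 1
elastic_net         z-scored profiles (sklearn baseline)        tuned
==================  ==========================================  =========
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .ensemble import BaggedEnsemble, fit_bagged
from .errors import ConfigError, StratificationError
from .pcr import GroupPCBasis, fit_group_pca, fit_pcr_sgl, transform_to_scores
from .preprocess import (
    ImputationPolicy,
    ScalerParams,
    apply_scaler,
    fit_scaler,
    impute_profiles,
    inverse_transform_predictions,
    transform_target,
)
from .profiles import GroupedFeatureMatrix, PhenotypeTarget
from .sgl import SGLHyperparams, fit_sgl, lambda_max

logger = logging.getLogger(__name__)

__all__ = [
    "ESTIMATORS",
    "FoldPlan",
    "SearchSpace",
    "CVConfig",
    "NestedCVResult",
    "make_fold_plan",
    "tune_hyperparams",
    "tune_by_ebic",
    "nested_cv",
    "randomization_test",
    "compute_metrics",
]

ESTIMATORS = (
    "sgl",
    "pcr_sgl",
    "lasso",
    "bundle_mean_lasso",
    "pcr_lasso",
    "elastic_net",
)
_TUNABLE_ALPHA = {"sgl", "pcr_sgl", "elastic_net"}


def _child_seed(seed: int, *path: int) -> int:
    """Deterministic fan-out of one master seed along an integer path."""
    ss = np.random.SeedSequence([int(seed), *[int(p) for p in path]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


# ---------------------------------------------------------------------------
# Fold plans
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Outer fold assignment plus, per outer fold, an inner assignment over
    that fold's training subjects."""

    outer: np.ndarray  # fold id per subject, length S
    inner: list  # inner[f][j] = inner fold of the j-th train subject of f
    k0: int
    k1: int
    stratified: bool
    seed: int

    def outer_split(self, f: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.outer == f)
        train = np.flatnonzero(self.outer != f)
        return train, test

    def inner_split(
        self, f: int, j: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Absolute subject indices of inner fold j within outer fold f."""
        train, _ = self.outer_split(f)
        mask = self.inner[f] == j
        return train[~mask], train[mask]


def make_fold_plan(
    S: int,
    k0: int,
    k1: int,
    labels: np.ndarray | None = None,
    seed: int = 0,
) -> FoldPlan:
    """Seeded, shuffled (optionally stratified) nested fold assignment.

    Outer fold sizes differ by at most one; with labels, per-fold class
    proportions match the whole within rounding (StratifiedKFold).
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    if k0 < 2 or k1 < 2:
        raise ConfigError("k0 and k1 must both be >= 2")
    if S < k0:
        raise ConfigError(f"cannot split {S} subjects into {k0} outer folds")
    stratified = labels is not None
    if stratified:
        labels = np.asarray(labels)
        counts = np.unique(labels, return_counts=True)[1]
        if counts.min() < k0:
            raise StratificationError(
                f"smallest class has {counts.min()} members < k0 = {k0}"
            )
        splitter = StratifiedKFold(
            n_splits=k0, shuffle=True, random_state=_child_seed(seed, 0)
        )
        split_iter = splitter.split(np.zeros(S), labels)
    else:
        splitter = KFold(
            n_splits=k0, shuffle=True, random_state=_child_seed(seed, 0)
        )
        split_iter = splitter.split(np.zeros(S))

    outer = np.empty(S, dtype=int)
    for f, (_, test) in enumerate(split_iter):
        outer[test] = f

    inner = []
    for f in range(k0):
        train = np.flatnonzero(outer != f)
        n_tr = len(train)
        assign = np.empty(n_tr, dtype=int)
        if stratified:
            lab = labels[train]
            inner_split = StratifiedKFold(
                n_splits=k1, shuffle=True,
                random_state=_child_seed(seed, 1, f),
            ).split(np.zeros(n_tr), lab)
        else:
            inner_split = KFold(
                n_splits=k1, shuffle=True,
                random_state=_child_seed(seed, 1, f),
            ).split(np.zeros(n_tr))
        for j, (_, test) in enumerate(inner_split):
            assign[test] = j
        inner.append(assign)
    return FoldPlan(
        outer=outer, inner=inner, k0=k0, k1=k1,
        stratified=stratified, seed=seed,
    )


# ---------------------------------------------------------------------------
# Pipelines (scaler + feature map + penalized fit), train-rows only
# ---------------------------------------------------------------------------

@dataclass
class FittedPipeline:
    """One estimator fitted on one training split."""

    name: str
    loss: str
    scaler: ScalerParams
    model: object  # SGLModel | PCRSGLModel | BaggedEnsemble | sklearn model
    alpha: float
    lam_ratio: float
    lam: float
    groups: list
    basis: GroupPCBasis | None = None  # pcr_lasso global basis
    group_means: bool = False

    def _features(self, X: np.ndarray) -> np.ndarray:
        Xs = apply_scaler(np.asarray(X, dtype=float), self.scaler)
        if self.group_means:
            return np.column_stack(
                [Xs[:, g].mean(axis=1) for g in self.groups]
            )
        if self.basis is not None:
            return transform_to_scores(Xs, self.basis)
        return Xs

    def predict_model_scale(self, X: np.ndarray) -> np.ndarray:
        F = self._features(X)
        if self.name == "elastic_net":
            if self.loss == "logistic":
                return self.model.predict_proba(F)[:, 1]
            return self.model.predict(F)
        if self.loss == "logistic":
            return (
                self.model.predict_proba(F)
                if hasattr(self.model, "predict_proba")
                else self.model.predict(F)
            )
        return self.model.predict(F)

    @property
    def coefficients_original_space(self) -> np.ndarray | None:
        """Coefficients mapped back to profile columns where well-defined
        (identity and group-wise-PC feature spaces)."""
        if self.name in ("sgl", "lasso", "pcr_sgl", "elastic_net"):
            c = getattr(self.model, "coefficients", None)
            if c is None:  # sklearn
                c = getattr(self.model, "coef_", None)
                if c is not None:
                    c = np.ravel(c)
            return c
        return None


def _fit_pipeline(
    name: str,
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    groups: list,
    loss: str,
    alpha: float,
    lam_ratio: float,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> FittedPipeline:
    """Fit scaler, feature map and penalized model on training rows only.

    ``y_tr`` is on the model scale (already transformed); ``lam_ratio``
    multiplies the lambda_max of the mapped training features.
    """
    if name not in ESTIMATORS:
        raise ConfigError(f"unknown estimator {name!r}")
    scaler = fit_scaler(X_tr)
    Xs = apply_scaler(np.asarray(X_tr, dtype=float), scaler)

    basis = None
    group_means = False
    if name in ("sgl", "lasso", "elastic_net"):
        F = Xs
        fg = groups if name == "sgl" else [np.array([j]) for j in
                                           range(Xs.shape[1])]
    elif name == "bundle_mean_lasso":
        group_means = True
        F = np.column_stack([Xs[:, g].mean(axis=1) for g in groups])
        fg = [np.array([j]) for j in range(F.shape[1])]
    elif name == "pcr_lasso":
        basis = fit_group_pca(Xs, [np.arange(Xs.shape[1])])
        F = transform_to_scores(Xs, basis)
        fg = [np.array([j]) for j in range(F.shape[1])]
    else:  # pcr_sgl handled by fit_pcr_sgl below
        F = Xs
        fg = groups

    eff_alpha = alpha if name in _TUNABLE_ALPHA else 1.0

    if name == "elastic_net":
        model, lam = _fit_elastic_net(F, y_tr, loss, eff_alpha, lam_ratio)
    elif name == "pcr_sgl":
        gb = fit_group_pca(F, fg)
        Z = transform_to_scores(F, gb)
        lam = lam_ratio * lambda_max(Z, y_tr, eff_alpha, gb.score_groups(),
                                     loss=loss)
        hp = SGLHyperparams(alpha=eff_alpha, lam=lam)
        model = fit_pcr_sgl(F, y_tr, hp, loss=loss, basis=gb,
                            tol=tol, max_iter=max_iter, keep_residuals=False)
    else:
        lam = lam_ratio * lambda_max(F, y_tr, eff_alpha, fg, loss=loss)
        hp = SGLHyperparams(alpha=eff_alpha, lam=lam)
        model = fit_sgl(F, y_tr, hp, fg, loss=loss, tol=tol,
                        max_iter=max_iter, keep_residuals=False)

    return FittedPipeline(
        name=name, loss=loss, scaler=scaler, model=model,
        alpha=eff_alpha, lam_ratio=lam_ratio, lam=lam,
        groups=groups, basis=basis, group_means=group_means,
    )


def _fit_elastic_net(F, y, loss, l1_ratio, lam_ratio):
    """sklearn elastic-net baseline; lambda anchored to the lasso-limit
    lambda_max of the same training features."""
    from sklearn.linear_model import ElasticNet, LogisticRegression

    singles = [np.array([j]) for j in range(F.shape[1])]
    l1 = min(max(l1_ratio, 1e-3), 1.0)  # sklearn requires l1_ratio > 0 here
    lam = lam_ratio * lambda_max(F, y, 1.0, singles, loss=loss)
    n = F.shape[0]
    if loss == "squared":
        model = ElasticNet(
            alpha=max(lam, 1e-12) / (n * l1), l1_ratio=l1,
            max_iter=50000, tol=1e-8,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(F, y)
    else:
        model = LogisticRegression(
            penalty="elasticnet", solver="saga", l1_ratio=l1,
            C=1.0 / max(lam, 1e-12), max_iter=20000, tol=1e-8,
        )
        model.fit(F, y)
    return model, lam


# ---------------------------------------------------------------------------
# Hyperparameter search
# ---------------------------------------------------------------------------

@dataclass
class SearchSpace:
    """Candidate space for (alpha, lambda-ratio).

    lambda is parametrized as ratio * lambda_max of the training split, with
    the ratio log-uniform; alpha is uniform on [0, 1] for tunable-alpha
    estimators.
    """

    alpha_grid: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    ratio_grid: tuple = tuple(float(r) for r in np.logspace(-3, 0, 7))
    alpha_bounds: tuple = (0.0, 1.0)
    ratio_bounds: tuple = (1e-3, 1.0)


@dataclass
class TuneResult:
    alpha: float
    lam_ratio: float
    score: float
    evaluations: list  # (alpha, ratio, mean inner score)


def _inner_score(
    name, X, y_model, groups, loss, transform, y_orig,
    inner_assign, train_abs, alpha, ratio, tol, max_iter,
) -> float:
    """Mean held-out score of one candidate over the inner folds.

    Regression is scored by R^2 on the original target scale, classification
    by accuracy — the quantities the outer evaluation reports.
    """
    from sklearn.metrics import accuracy_score, r2_score

    scores = []
    for j in range(int(inner_assign.max()) + 1):
        tr = train_abs[inner_assign != j]
        te = train_abs[inner_assign == j]
        try:
            pipe = _fit_pipeline(
                name, X[tr], y_model[tr], groups, loss, alpha, ratio,
                tol=tol, max_iter=max_iter,
            )
            pred = pipe.predict_model_scale(X[te])
        except Exception:  # degenerate candidate (e.g. singular resample)
            return -np.inf
        if loss == "logistic":
            scores.append(accuracy_score(y_orig[te], pred >= 0.5))
        else:
            scores.append(
                r2_score(y_orig[te],
                         inverse_transform_predictions(pred, transform))
            )
    return float(np.mean(scores))


def tune_hyperparams(
    X: np.ndarray,
    y_model: np.ndarray,
    groups: list,
    inner_assign: np.ndarray,
    train_abs: np.ndarray,
    estimator: str = "sgl",
    loss: str = "squared",
    transform: str = "identity",
    y_orig: np.ndarray | None = None,
    method: str = "grid",
    budget: int = 50,
    search_space: SearchSpace | None = None,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> TuneResult:
    """Select (alpha, lambda-ratio) maximizing the mean inner-fold score.

    ``grid`` is exhaustive and deterministic over the space's grids;
    ``smbo`` is seeded sequential model-based optimization (GP surrogate,
    expected-improvement acquisition) over the space's continuous bounds.
    If every candidate degenerates, the most regularized candidate (largest
    ratio) is returned with a warning.
    """
    space = search_space or SearchSpace()
    if budget < 1:
        raise ConfigError("budget must be >= 1")
    if y_orig is None:
        y_orig = inverse_transform_predictions(y_model, transform)
    tunable = estimator in _TUNABLE_ALPHA

    def score_at(alpha, ratio):
        return _inner_score(
            estimator, X, y_model, groups, loss, transform, y_orig,
            inner_assign, train_abs, alpha, ratio, tol, max_iter,
        )

    if method == "grid":
        alphas = tuple(space.alpha_grid) if tunable else (1.0,)
        cands = [(a, r) for a in alphas for r in space.ratio_grid]
    elif method == "smbo":
        cands = None
    else:
        raise ConfigError(f"unknown tuning method {method!r}")

    evals = []
    if cands is not None:
        for a, r in cands:
            evals.append((a, r, score_at(a, r)))
    else:
        evals = _smbo(
            score_at, tunable, space, budget, seed,
        )

    scores = np.array([e[2] for e in evals])
    if not np.any(np.isfinite(scores)):
        warnings.warn(
            "all hyperparameter candidates degenerated; returning the most "
            "regularized candidate", RuntimeWarning, stacklevel=2,
        )
        best = int(np.argmax([e[1] for e in evals]))
    else:
        best = int(np.argmax(scores))
    a, r, s = evals[best]
    return TuneResult(alpha=a, lam_ratio=r, score=s, evaluations=evals)


def tune_by_ebic(
    X: np.ndarray,
    y_model: np.ndarray,
    groups: list,
    estimator: str = "sgl",
    loss: str = "squared",
    gamma: float = 1.0,
    search_space: SearchSpace | None = None,
    tol: float = 1e-4,
    max_iter: int = 2000,
) -> TuneResult:
    """Select (alpha, lambda-ratio) minimizing the extended BIC.

    Cross-validated predictive tuning deliberately under-regularizes: the
    lambda that minimizes prediction error is known not to be
    model-selection consistent, so CV-tuned fits include spurious groups
    with small coefficients.  For support-recovery questions ("which
    bundles carry signal?") the extended Bayesian information criterion
    (EBIC) is the standard consistent alternative in the p > n regime:

        EBIC = n log(RSS / n) + df (log n + 2 gamma log P)     (squared)
        EBIC = 2 NLL + df (log n + 2 gamma log P)              (logistic)

    with df the number of nonzero coefficients and gamma in [0, 1] the
    dimensionality penalty (gamma = 0 recovers plain BIC; gamma = 1 is the
    conservative default for P >> n).  Candidates are fitted on the full
    training split; no inner folds are needed.
    """
    space = search_space or SearchSpace()
    X = np.asarray(X, dtype=float)
    y_model = np.asarray(y_model, dtype=float)
    n, P = X.shape
    tunable = estimator in _TUNABLE_ALPHA
    alphas = tuple(space.alpha_grid) if tunable else (1.0,)
    evals = []
    for a in alphas:
        for r in space.ratio_grid:
            try:
                pipe = _fit_pipeline(
                    estimator, X, y_model, groups, loss, a, r,
                    tol=tol, max_iter=max_iter,
                )
            except Exception:
                evals.append((a, r, np.inf))
                continue
            pred = pipe.predict_model_scale(X)
            coefs = pipe.coefficients_original_space
            if coefs is None:
                coefs = getattr(pipe.model, "coefficients", np.zeros(1))
            df = int(np.sum(np.asarray(coefs) != 0))
            if loss == "squared":
                rss = max(float(np.sum((y_model - pred) ** 2)), 1e-300)
                fit_term = n * np.log(rss / n)
            else:
                eps = 1e-12
                p_hat = np.clip(pred, eps, 1 - eps)
                nll = -float(
                    np.sum(y_model * np.log(p_hat)
                           + (1 - y_model) * np.log(1 - p_hat))
                )
                fit_term = 2.0 * nll
            ebic = fit_term + df * (np.log(n) + 2.0 * gamma * np.log(P))
            evals.append((a, r, float(ebic)))
    crit = np.array([e[2] for e in evals])
    best = int(np.argmin(crit))
    a, r, c = evals[best]
    return TuneResult(alpha=a, lam_ratio=r, score=-c, evaluations=evals)


def _smbo(score_at, tunable, space: SearchSpace, budget: int, seed: int):
    """GP-surrogate sequential optimization with expected improvement."""
    from scipy.stats import norm
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern, WhiteKernel

    rng = np.random.default_rng(_child_seed(seed, 7))
    lo_r, hi_r = np.log10(space.ratio_bounds[0]), np.log10(space.ratio_bounds[1])
    lo_a, hi_a = space.alpha_bounds

    def sample(n):
        r = rng.uniform(lo_r, hi_r, size=n)
        a = rng.uniform(lo_a, hi_a, size=n) if tunable else np.ones(n)
        return np.column_stack([a, r])

    n_init = min(budget, max(4, budget // 4))
    pts = sample(n_init)
    evals = [
        (float(a), float(10.0**r), score_at(float(a), float(10.0**r)))
        for a, r in pts
    ]
    while len(evals) < budget:
        Xo = np.array([[a, np.log10(r)] for a, r, _ in evals])
        yo = np.array([s for _, _, s in evals])
        finite = np.isfinite(yo)
        if finite.sum() < 2:
            a, r = sample(1)[0]
            evals.append((float(a), float(10.0**r), score_at(a, 10.0**r)))
            continue
        yo = np.where(finite, yo, yo[finite].min() - 1.0)
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5, length_scale=[0.5, 1.0])
            + WhiteKernel(1e-4),
            normalize_y=True,
            random_state=_child_seed(seed, 8, len(evals)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(Xo, yo)
        pool = sample(256)
        mu, sd = gp.predict(pool, return_std=True)
        best = yo.max()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (mu - best) / np.where(sd > 0, sd, 1.0)
            ei = np.where(
                sd > 0, (mu - best) * norm.cdf(z) + sd * norm.pdf(z), 0.0
            )
        a, r = pool[int(np.argmax(ei))]
        evals.append((float(a), float(10.0**r), score_at(float(a),
                                                         float(10.0**r))))
    return evals


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVConfig:
    """Everything a nested-CV run needs besides the data."""

    estimator: str = "sgl"
    k0: int = 10
    k1: int = 3
    tuner: str = "grid"  # "grid" | "smbo"
    budget: int = 50
    search_space: SearchSpace = field(default_factory=SearchSpace)
    bag_m: int = 0  # 0 or 1: no bagging
    seed: int = 0
    tol: float = 1e-6
    max_iter: int = 2000
    imputation: ImputationPolicy = field(default_factory=ImputationPolicy)

    def __post_init__(self):
        if self.estimator not in ESTIMATORS:
            raise ConfigError(f"unknown estimator {self.estimator!r}")
        if self.tuner not in ("grid", "smbo"):
            raise ConfigError(f"unknown tuner {self.tuner!r}")
        if self.bag_m < 0:
            raise ConfigError("bag_m must be >= 0")


@dataclass
class NestedCVResult:
    plan: FoldPlan
    fold_records: list  # per outer fold: dict with alpha, lam_ratio, lam, ...
    predictions: np.ndarray  # out-of-fold, original target scale
    proba: np.ndarray | None  # out-of-fold class-1 probabilities
    metrics: dict  # pooled out-of-fold metrics
    per_fold_metrics: list
    mean_alpha: float
    mean_lam: float
    mean_coefficients: np.ndarray | None  # mean over folds, original space

    @property
    def headline(self) -> float:
        return self.metrics["accuracy" if self.proba is not None
                            else "r2"]


def nested_cv(
    matrix: GroupedFeatureMatrix,
    target: PhenotypeTarget,
    config: CVConfig,
) -> NestedCVResult:
    """Run the full nested-CV pipeline and pool out-of-fold predictions.

    Per outer fold: tune (alpha, lambda-ratio) on the inner folds (each
    candidate refits scaler/basis on its inner training rows), refit on the
    full outer training set (optionally as a bagged ensemble sharing the
    tuned hyperparameters), and predict the held-out fold.  Metrics are
    computed once from the pooled out-of-fold predictions, on the original
    target scale.
    """
    matrix = impute_profiles(matrix, config.imputation)
    X = matrix.values
    groups = matrix.groups
    S = X.shape[0]
    loss = "logistic" if target.kind == "binary" else "squared"
    transform = target.transform
    y_model = transform_target(target)
    y_orig = target.values
    labels = y_orig if target.kind == "binary" else None

    plan = make_fold_plan(S, config.k0, config.k1, labels=labels,
                          seed=config.seed)
    predictions = np.full(S, np.nan)
    proba = np.full(S, np.nan) if loss == "logistic" else None
    fold_records = []
    per_fold_metrics = []
    coef_sum, coef_n = None, 0

    for f in range(config.k0):
        train, test = plan.outer_split(f)
        tune = tune_hyperparams(
            X, y_model, groups, plan.inner[f], train,
            estimator=config.estimator, loss=loss, transform=transform,
            y_orig=y_orig, method=config.tuner, budget=config.budget,
            search_space=config.search_space,
            seed=_child_seed(config.seed, 2, f),
            tol=config.tol, max_iter=config.max_iter,
        )

        if config.bag_m and config.bag_m > 1:
            def base_fit(Xb, yb):
                pipe = _fit_pipeline(
                    config.estimator, Xb, yb, groups, loss,
                    tune.alpha, tune.lam_ratio,
                    tol=config.tol, max_iter=config.max_iter,
                )
                return _PipelineAsModel(pipe)

            ens = fit_bagged(
                base_fit, X[train], y_model[train], m=config.bag_m,
                seed=_child_seed(config.seed, 3, f), loss=loss,
            )
            pred_model = np.mean(
                [m.pipe.predict_model_scale(X[test]) for m in ens.models],
                axis=0,
            )
            alpha_f = ens.alpha
            lam_f = ens.lam
            coefs = _mean_original_coefs(ens)
        else:
            pipe = _fit_pipeline(
                config.estimator, X[train], y_model[train], groups, loss,
                tune.alpha, tune.lam_ratio,
                tol=config.tol, max_iter=config.max_iter,
            )
            pred_model = pipe.predict_model_scale(X[test])
            alpha_f, lam_f = pipe.alpha, pipe.lam
            coefs = pipe.coefficients_original_space

        if loss == "logistic":
            proba[test] = pred_model
            predictions[test] = (pred_model >= 0.5).astype(float)
        else:
            predictions[test] = inverse_transform_predictions(
                pred_model, transform
            )
        fm = compute_metrics(
            y_orig[test], predictions[test],
            task=target.kind,
            proba=None if proba is None else proba[test],
        )
        per_fold_metrics.append(fm)
        fold_records.append(
            {
                "fold": f,
                "alpha": float(alpha_f),
                "lam_ratio": float(tune.lam_ratio),
                "lam": float(lam_f),
                "inner_score": float(tune.score),
                "n_train": int(len(train)),
                "coefficients": coefs,
            }
        )
        if coefs is not None:
            coef_sum = coefs.copy() if coef_sum is None else coef_sum + coefs
            coef_n += 1

    metrics = compute_metrics(
        y_orig, predictions, task=target.kind, proba=proba
    )
    return NestedCVResult(
        plan=plan,
        fold_records=fold_records,
        predictions=predictions,
        proba=proba,
        metrics=metrics,
        per_fold_metrics=per_fold_metrics,
        mean_alpha=float(np.mean([r["alpha"] for r in fold_records])),
        mean_lam=float(np.mean([r["lam"] for r in fold_records])),
        mean_coefficients=None if coef_n == 0 else coef_sum / coef_n,
    )


class _PipelineAsModel:
    """Adapter giving a FittedPipeline the constituent-model surface the
    bagging aggregator expects."""

    def __init__(self, pipe: FittedPipeline):
        self.pipe = pipe
        inner = pipe.model
        c = pipe.coefficients_original_space
        self.coefficients = (
            c if c is not None else np.atleast_1d(getattr(inner, "coefficients",
                                                          np.array([0.0])))
        )
        self.intercept = float(getattr(inner, "intercept", 0.0))
        self.hyperparams = SGLHyperparams(alpha=pipe.alpha, lam=pipe.lam)

    def predict(self, X):
        return self.pipe.predict_model_scale(X)

    def predict_proba(self, X):
        return self.pipe.predict_model_scale(X)


def _mean_original_coefs(ens: BaggedEnsemble) -> np.ndarray | None:
    coefs = [m.pipe.coefficients_original_space for m in ens.models]
    if any(c is None for c in coefs):
        return None
    return np.mean(coefs, axis=0)


# ---------------------------------------------------------------------------
# Metrics and the randomization test
# ---------------------------------------------------------------------------

def compute_metrics(
    y_true: np.ndarray,
    predictions: np.ndarray,
    task: str = "continuous",
    proba: np.ndarray | None = None,
) -> dict:
    """Regression: R^2, MAE, median absolute error (original scale).
    Classification: accuracy, ROC AUC from probabilities (None + warning
    when y_true has a single class)."""
    from sklearn.metrics import (
        accuracy_score,
        mean_absolute_error,
        median_absolute_error,
        r2_score,
        roc_auc_score,
    )

    y_true = np.asarray(y_true, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if y_true.shape != predictions.shape:
        raise ValueError("y_true and predictions must have equal length")
    if task == "continuous":
        return {
            "r2": float(r2_score(y_true, predictions)),
            "mae": float(mean_absolute_error(y_true, predictions)),
            "median_ae": float(median_absolute_error(y_true, predictions)),
        }
    out = {"accuracy": float(accuracy_score(y_true, predictions))}
    if proba is not None:
        if len(np.unique(y_true)) < 2:
            warnings.warn(
                "ROC AUC undefined for single-class y_true",
                RuntimeWarning, stacklevel=2,
            )
            out["roc_auc"] = None
        else:
            out["roc_auc"] = float(roc_auc_score(y_true, proba))
    return out


def randomization_test(
    matrix: GroupedFeatureMatrix,
    target: PhenotypeTarget,
    config: CVConfig,
    n_shuffles: int = 20,
    seed: int = 0,
) -> dict:
    """Null distribution of the headline metric under target shuffling.

    Refits the entire nested-CV pipeline on copies of the data whose target
    rows are randomly permuted (features fixed), destroying any true
    feature-target relationship.  Returns the observed metric, the null
    values, and the observed metric's empirical quantile within the null.
    """
    if n_shuffles < 1:
        raise ConfigError("n_shuffles must be >= 1")
    observed = nested_cv(matrix, target, config)
    key = "accuracy" if target.kind == "binary" else "r2"
    null = []
    for s in range(n_shuffles):
        rng = np.random.default_rng(_child_seed(seed, 4, s))
        perm = rng.permutation(len(target.values))
        shuffled = PhenotypeTarget(
            values=target.values[perm],
            kind=target.kind,
            transform=target.transform,
            subject_ids=target.subject_ids,
        )
        res = nested_cv(matrix, shuffled, config)
        null.append(res.metrics[key])
    null = np.asarray(null, dtype=float)
    obs = observed.metrics[key]
    return {
        "metric": key,
        "observed": obs,
        "null": null,
        "quantile": float(np.mean(null <= obs)),
        "observed_result": observed,
    }
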