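"""Sparse group lasso (SGL) estimation by proximal gradient descent.

The SGL solves, for a design matrix ``X`` whose columns are partitioned into
``G`` disjoint groups,

    min_beta  L(beta) + (1 - alpha) * lam * sum_l w_l ||beta^(l)||_2
                       + alpha * lam * ||beta||_1

where ``L`` is either the squared-error loss ``0.5 * ||y - b0 - X beta||^2``
or the logistic cross-entropy loss (sum over samples, no 1/n factor; the
regularization strength ``lam`` therefore scales with the sample size, and
:func:`lambda_max` gives a scale-free anchor for search ranges).

``alpha = 1`` recovers the lasso, ``alpha = 0`` the group lasso.  The group
weights default to ``sqrt(p_l)`` so that equal-sized groups are
weight-neutral.  The intercept is never penalized: for squared error it is
handled by centering, for logistic loss as an explicit extra coordinate.

The solver is FISTA with backtracking line search and a monotone safeguard
(a momentum step that would increase the objective falls back to a plain
proximal-gradient step and restarts the momentum), terminating on the
max-norm of the minimal KKT subgradient residual.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SGLHyperparams",
    "SGLModel",
    "FitRecord",
    "default_group_weights",
    "sgl_penalty",
    "sgl_prox",
    "lambda_max",
    "kkt_residual",
    "fit_sgl",
    "predict",
    "predict_proba",
]

VALID_LOSSES = ("squared", "logistic")


def _as_group_arrays(groups) -> list[np.ndarray]:
    return [np.asarray(g, dtype=np.intp) for g in groups]


def check_groups(groups, n_features: int) -> list[np.ndarray]:
    """Validate that ``groups`` partitions ``range(n_features)``."""
    gs = _as_group_arrays(groups)
    if any(g.size == 0 for g in gs):
        raise ValueError("empty group in partition")
    all_idx = np.concatenate(gs) if gs else np.array([], dtype=np.intp)
    if len(all_idx) != n_features or not np.array_equal(
        np.sort(all_idx), np.arange(n_features)
    ):
        raise ValueError(
            f"groups must partition the {n_features} feature columns exactly"
        )
    return gs


def default_group_weights(groups) -> np.ndarray:
    """Standard SGL convention: w_l = sqrt(p_l)."""
    return np.array([np.sqrt(len(g)) for g in groups], dtype=float)


@dataclass
class SGLHyperparams:
    """Mixing parameter, strength, and per-group weights of the SGL penalty.

    alpha
        Lasso / group-lasso mixing in [0, 1]; 1 is pure lasso, 0 pure
        group lasso.
    lam
        Overall regularization strength, >= 0, on the scale of the
        unnormalized loss (no 1/n).
    group_weights
        Positive per-group weights; ``None`` means sqrt(group size).
    """

    alpha: float
    lam: float
    group_weights: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.group_weights is not None:
            self.group_weights = np.asarray(self.group_weights, dtype=float)
            if np.any(self.group_weights <= 0):
                raise ValueError("all group weights must be > 0")

    def weights_for(self, groups) -> np.ndarray:
        if self.group_weights is None:
            return default_group_weights(groups)
        w = self.group_weights
        if len(w) != len(groups):
            raise ValueError(
                f"{len(w)} group weights for {len(groups)} groups"
            )
        return w


@dataclass
class FitRecord:
    iterations: int
    objective: float
    kkt: float
    tol: float
    converged: bool
    residuals: np.ndarray | None = None  # training residuals y - yhat


@dataclass
class SGLModel:
    """A fitted sparse group lasso model."""

    coefficients: np.ndarray
    intercept: float
    loss: str
    hyperparams: SGLHyperparams
    groups: list = field(default_factory=list)
    fit_record: FitRecord | None = None

    def group_coefficients(self, ell: int) -> np.ndarray:
        return self.coefficients[self.groups[ell]]

    @property
    def active_groups_(self) -> np.ndarray:
        """Indices of groups with at least one nonzero coefficient."""
        return np.array(
            [i for i, g in enumerate(self.groups)
             if np.any(self.coefficients[g] != 0)],
            dtype=int,
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return predict_proba(self, X)

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        rec = self.fit_record
        return json.dumps(
            {
                "coefficients": self.coefficients.tolist(),
                "intercept": float(self.intercept),
                "loss": self.loss,
                "alpha": self.hyperparams.alpha,
                "lam": self.hyperparams.lam,
                "group_weights": (
                    None
                    if self.hyperparams.group_weights is None
                    else self.hyperparams.group_weights.tolist()
                ),
                "groups": [np.asarray(g).tolist() for g in self.groups],
                "fit_record": None
                if rec is None
                else {
                    "iterations": rec.iterations,
                    "objective": rec.objective,
                    "kkt": rec.kkt,
                    "tol": rec.tol,
                    "converged": rec.converged,
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SGLModel":
        d = json.loads(text)
        rec = d.get("fit_record")
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            loss=d["loss"],
            hyperparams=SGLHyperparams(
                alpha=d["alpha"],
                lam=d["lam"],
                group_weights=d["group_weights"],
            ),
            groups=[np.asarray(g, dtype=np.intp) for g in d["groups"]],
            fit_record=None if rec is None else FitRecord(**rec, residuals=None),
        )


# ---------------------------------------------------------------------------
# Penalty and proximal operator
# ---------------------------------------------------------------------------

def sgl_penalty(beta: np.ndarray, groups, hp: SGLHyperparams) -> float:
    """Value of the SGL penalty at ``beta``."""
    beta = np.asarray(beta, dtype=float)
    gs = _as_group_arrays(groups)
    w = hp.weights_for(gs)
    group_term = sum(
        w[ell] * np.linalg.norm(beta[g]) for ell, g in enumerate(gs)
    )
    return (1.0 - hp.alpha) * hp.lam * group_term + hp.alpha * hp.lam * np.sum(
        np.abs(beta)
    )


def _soft_threshold(v: np.ndarray, thresh: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - thresh, 0.0)


def sgl_prox(v: np.ndarray, step: float, hp: SGLHyperparams, groups) -> np.ndarray:
    """Exact proximal operator of ``step * penalty`` at ``v``.

    Closed form: elementwise soft-threshold at ``step*alpha*lam``, then
    per-group norm shrinkage at ``step*(1-alpha)*lam*w_l`` (group zeroed
    when the soft-thresholded norm falls below the group threshold).
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    v = np.asarray(v, dtype=float)
    gs = _as_group_arrays(groups)
    w = hp.weights_for(gs)
    out = _soft_threshold(v, step * hp.alpha * hp.lam)
    group_lam = step * (1.0 - hp.alpha) * hp.lam
    if group_lam > 0:
        for ell, g in enumerate(gs):
            nrm = np.linalg.norm(out[g])
            thr = group_lam * w[ell]
            if nrm <= thr:
                out[g] = 0.0
            else:
                out[g] *= 1.0 - thr / nrm
    return out


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _log_loss(y: np.ndarray, z: np.ndarray) -> float:
    # sum_i log(1 + exp(z_i)) - y_i z_i, numerically stable
    return float(np.sum(np.logaddexp(0.0, z) - y * z))


# ---------------------------------------------------------------------------
# lambda_max
# ---------------------------------------------------------------------------

def _grad_at_zero(X: np.ndarray, y: np.ndarray, loss: str) -> np.ndarray:
    """Loss gradient w.r.t. beta at beta = 0 with the intercept at its
    unpenalized optimum."""
    if loss == "squared":
        return X.T @ (np.mean(y) - y)
    elif loss == "logistic":
        pbar = np.mean(y)
        return X.T @ (np.full_like(y, pbar, dtype=float) - y)
    raise ValueError(f"unknown loss {loss!r}")


def lambda_max(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    groups,
    loss: str = "squared",
    group_weights: np.ndarray | None = None,
) -> float:
    """Smallest lam at which the all-zero coefficient vector is optimal.

    Derived from the subgradient condition at beta = 0: the zero solution is
    optimal iff for every group ``||soft(g^(l), alpha*lam)||_2 <=
    (1-alpha)*lam*w_l`` where ``g`` is the intercept-adjusted loss gradient.
    """
    from scipy.optimize import brentq

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    gs = check_groups(groups, X.shape[1])
    hp = SGLHyperparams(alpha=alpha, lam=1.0, group_weights=group_weights)
    w = hp.weights_for(gs)
    if alpha == 0.0 and np.any(w <= 0):
        raise ValueError("alpha = 0 requires strictly positive group weights")

    g = _grad_at_zero(X, y, loss)
    gmax = np.max(np.abs(g)) if g.size else 0.0
    if gmax == 0.0:
        return 0.0
    if alpha == 1.0:
        return float(gmax)
    if alpha == 0.0:
        return float(
            max(np.linalg.norm(g[idx]) / w[ell] for ell, idx in enumerate(gs))
        )

    lam_star = 0.0
    for ell, idx in enumerate(gs):
        gl = g[idx]
        if not np.any(gl):
            continue

        def excess(lam, gl=gl, wl=w[ell]):
            return (
                np.linalg.norm(_soft_threshold(gl, alpha * lam))
                - (1.0 - alpha) * lam * wl
            )

        hi = np.max(np.abs(gl)) / alpha  # soft() == 0 beyond this point
        if excess(hi) >= 0:
            root = hi
        else:
            root = brentq(excess, 0.0, hi, xtol=1e-14, rtol=1e-14)
        lam_star = max(lam_star, root)
    return float(lam_star)


# ---------------------------------------------------------------------------
# KKT residual
# ---------------------------------------------------------------------------

def kkt_residual(
    X: np.ndarray,
    y: np.ndarray,
    beta: np.ndarray,
    intercept: float,
    hp: SGLHyperparams,
    groups,
    loss: str = "squared",
) -> float:
    """Max-norm of the minimal subgradient of the objective at (intercept, beta).

    Zero at the exact optimum; used as the solver's stopping criterion and
    verifiable post hoc.  Includes the intercept stationarity term.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    gs = _as_group_arrays(groups)
    w = hp.weights_for(gs)
    if loss == "squared":
        r = y - intercept - X @ beta
        g = -(X.T @ r)
        g0 = -np.sum(r)
    elif loss == "logistic":
        p = _sigmoid(intercept + X @ beta)
        g = X.T @ (p - y)
        g0 = np.sum(p - y)
    else:
        raise ValueError(f"unknown loss {loss!r}")

    a_lam = hp.alpha * hp.lam
    b_lam = (1.0 - hp.alpha) * hp.lam
    res = abs(g0)
    for ell, idx in enumerate(gs):
        gl = g[idx]
        bl = beta[idx]
        thr = b_lam * w[ell]
        if not np.any(bl):
            # group at zero: minimal residual of the inclusion
            # 0 in g + a_lam*[-1,1]^p + thr*B2
            excess = max(0.0, np.linalg.norm(_soft_threshold(gl, a_lam)) - thr)
            res = max(res, excess)
        else:
            u = gl + thr * bl / np.linalg.norm(bl)
            nz = bl != 0
            res = max(res, np.max(np.abs(u[nz] + a_lam * np.sign(bl[nz]))))
            if np.any(~nz):
                res = max(res, np.max(np.maximum(np.abs(u[~nz]) - a_lam, 0.0)))
    return float(res)


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

def _spectral_norm_sq(A: np.ndarray, n_iter: int = 50, seed: int = 0) -> float:
    """Power-iteration estimate of ||A||_2^2."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(A.shape[1])
    v /= np.linalg.norm(v)
    s = 1.0
    for _ in range(n_iter):
        u = A @ v
        v = A.T @ u
        s = np.linalg.norm(v)
        if s == 0:
            return 1.0
        v /= s
    return float(s)


def fit_sgl(
    X: np.ndarray,
    y: np.ndarray,
    hp: SGLHyperparams,
    groups,
    loss: str = "squared",
    max_iter: int = 5000,
    tol: float = 1e-7,
    warm_start: np.ndarray | None = None,
    keep_residuals: bool = True,
) -> SGLModel:
    """Fit an SGL model by monotone FISTA with backtracking line search.

    ``X`` must be complete (no NaN) and on the scale the caller intends
    (typically z-scored); ``y`` is on the model scale (already transformed).
    For the logistic loss ``y`` must be 0/1.  The fit is deterministic for
    fixed inputs.  Non-convergence within ``max_iter`` returns the model
    with ``fit_record.converged = False`` and a warning, never silently.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite (impute before fitting)")
    if loss not in VALID_LOSSES:
        raise ValueError(f"loss must be one of {VALID_LOSSES}")
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError(f"y has length {y.shape[0]}, X has {n} rows")
    gs = check_groups(groups, p)
    if loss == "logistic" and not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("logistic loss requires y in {0, 1}")

    if loss == "squared":
        # intercept via centering: solve on (Xc, yc), recover b0 afterwards
        x_mean = X.mean(axis=0)
        y_mean = float(np.mean(y))
        Xc = X - x_mean
        yc = y - y_mean

        def f_grad(b):
            r = Xc @ b - yc
            return 0.5 * float(r @ r), Xc.T @ r

        def f_val(b):
            r = Xc @ b - yc
            return 0.5 * float(r @ r)

        L0 = _spectral_norm_sq(Xc)
        dim = p
    else:
        # explicit unpenalized intercept as coordinate 0 of the working vector
        def f_grad(bb):
            z = bb[0] + X @ bb[1:]
            pr = _sigmoid(z)
            return _log_loss(y, z), np.concatenate(
                ([np.sum(pr - y)], X.T @ (pr - y))
            )

        def f_val(bb):
            return _log_loss(y, bb[0] + X @ bb[1:])

        X1 = np.column_stack([np.ones(n), X])
        L0 = 0.25 * _spectral_norm_sq(X1)
        dim = p + 1

    # groups index into beta (excluding intercept); the logistic working
    # vector carries the intercept at position 0, never penalized
    def prox_full(v, step):
        if loss == "squared":
            return sgl_prox(v, step, hp, gs)
        out = v.copy()
        out[1:] = sgl_prox(v[1:], step, hp, gs)
        return out

    def beta_of(b):
        return b if loss == "squared" else b[1:]

    def intercept_of(b):
        if loss == "squared":
            return y_mean - float(x_mean @ b)
        return float(b[0])

    def objective(b):
        return f_val(b) + sgl_penalty(beta_of(b), gs, hp)

    b = np.zeros(dim) if warm_start is None else _init_warm(
        warm_start, dim, loss
    )
    step = 1.0 / max(L0, 1e-12)
    zk = b.copy()
    tk = 1.0
    obj = objective(b)
    kkt = np.inf
    it = 0
    check_every = 10
    for it in range(1, max_iter + 1):
        fz, gz = f_grad(zk)
        # backtracking on the majorizer at zk
        while True:
            b_new = prox_full(zk - step * gz, step)
            diff = b_new - zk
            quad = fz + float(gz @ diff) + float(diff @ diff) / (2.0 * step)
            if f_val(b_new) <= quad + 1e-12 * max(1.0, abs(quad)):
                break
            step *= 0.5
            if step < 1e-18:
                break
        obj_new = objective(b_new)
        if obj_new > obj:  # monotone safeguard: plain prox step + restart
            fb, gb = f_grad(b)
            b_new = prox_full(b - step * gb, step)
            obj_new = min(objective(b_new), obj)
            tk = 1.0
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        zk = b_new + ((tk - 1.0) / t_new) * (b_new - b)
        b, tk, obj = b_new, t_new, obj_new
        if it % check_every == 0 or it == max_iter:
            if loss == "squared":
                kkt = kkt_residual(
                    X, y, b, intercept_of(b), hp, gs, loss="squared"
                )
            else:
                kkt = kkt_residual(
                    X, y, b[1:], b[0], hp, gs, loss="logistic"
                )
            if kkt <= tol:
                break

    converged = kkt <= tol
    if not converged:
        warnings.warn(
            f"SGL did not reach KKT tolerance {tol:g} in {it} iterations "
            f"(residual {kkt:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    beta = beta_of(b).copy()
    b0 = intercept_of(b)
    if loss == "squared":
        resid = y - b0 - X @ beta
    else:
        resid = y - _sigmoid(b0 + X @ beta)
    return SGLModel(
        coefficients=beta,
        intercept=b0,
        loss=loss,
        hyperparams=hp,
        groups=gs,
        fit_record=FitRecord(
            iterations=it,
            objective=float(obj),
            kkt=float(kkt),
            tol=tol,
            converged=bool(converged),
            residuals=resid if keep_residuals else None,
        ),
    )


def _init_warm(warm: np.ndarray, dim: int, loss: str) -> np.ndarray:
    warm = np.asarray(warm, dtype=float)
    if warm.shape[0] == dim:
        return warm.copy()
    if loss == "logistic" and warm.shape[0] == dim - 1:
        return np.concatenate([[0.0], warm])
    raise ValueError("warm_start has wrong length")


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _check_X(model: SGLModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.coefficients.shape[0]:
        raise ValueError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} columns, model "
            f"expects {model.coefficients.shape[0]}"
        )
    return X


def predict(model: SGLModel, X: np.ndarray) -> np.ndarray:
    """Linear prediction (regression) or 0/1 class labels (logistic)."""
    X = _check_X(model, X)
    eta = model.intercept + X @ model.coefficients
    if model.loss == "squared":
        return eta
    return (_sigmoid(eta) >= 0.5).astype(float)


def predict_proba(model: SGLModel, X: np.ndarray) -> np.ndarray:
    """Class-1 probability under the logistic model."""
    if model.loss != "logistic":
        raise ValueError("predict_proba requires a logistic-loss model")
    X = _check_X(model, X)
    return _sigmoid(model.intercept + X @ model.coefficients)
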