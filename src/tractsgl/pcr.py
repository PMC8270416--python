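"""Group-wise principal-component projection and the PCR-SGL estimator.

Each (bundle, metric) block of the design matrix is independently reduced to
its compact SVD, X^(l) = U S V^T, and the SGL is fitted in the score space
Z^(l) = X^(l) V^(l).  Because the decomposition is per group, the grouping
structure survives the transformation, and score-space coefficients
back-project exactly: beta^(l) = V^(l) theta^(l), so predictions from theta
in score space and from beta in feature space are algebraically identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, StructuralError
from .sgl import SGLHyperparams, SGLModel, check_groups, fit_sgl

__all__ = [
    "GroupPCBasis",
    "PCRSGLModel",
    "fit_group_pca",
    "transform_to_scores",
    "fit_pcr_sgl",
]

RANK_TOL = 1e-12  # relative singular-value cutoff of the compact SVD


@dataclass
class GroupPCBasis:
    """Per-group principal axes and singular values, fitted on train rows."""

    axes: list  # V^(l): p_l x r_l, orthonormal columns
    singular_values: list  # length-r_l nonincreasing arrays
    groups: list  # original feature-space column index arrays
    n_train: int

    @property
    def ranks(self) -> list:
        return [v.shape[1] for v in self.axes]

    def score_groups(self) -> list:
        """Column partition of the score matrix, sizes r_l."""
        out, start = [], 0
        for r in self.ranks:
            out.append(np.arange(start, start + r, dtype=np.intp))
            start += r
        return out


def fit_group_pca(X_train: np.ndarray, groups) -> GroupPCBasis:
    """Compact SVD of every group block, sign-fixed for reproducibility.

    Singular values below ``RANK_TOL`` times the group's largest are
    dropped (numerical rank), so reconstruction from the retained factors
    is exact to floating precision.  Axis signs are fixed by making each
    axis's largest-magnitude loading positive.
    """
    X_train = np.asarray(X_train, dtype=float)
    gs = check_groups(groups, X_train.shape[1])
    axes, svals = [], []
    for g in gs:
        block = X_train[:, g]
        if block.shape[1] == 0:
            raise StructuralError("group with zero columns")
        U, s, Vt = np.linalg.svd(block, full_matrices=False)
        if s.size and s[0] > 0:
            r = int(np.sum(s > RANK_TOL * s[0]))
        else:
            r = 0
        V = Vt[:r].T
        # sign convention: largest |loading| of each axis positive
        for j in range(r):
            k = int(np.argmax(np.abs(V[:, j])))
            if V[k, j] < 0:
                V[:, j] = -V[:, j]
        axes.append(V)
        svals.append(s[:r].copy())
    return GroupPCBasis(
        axes=axes, singular_values=svals, groups=gs, n_train=X_train.shape[0]
    )


def transform_to_scores(X: np.ndarray, basis: GroupPCBasis) -> np.ndarray:
    """Project each group block onto its principal axes: Z^(l) = X^(l) V^(l)."""
    X = np.asarray(X, dtype=float)
    total_p = sum(len(g) for g in basis.groups)
    if X.shape[1] != total_p:
        raise DimensionError(
            f"X has {X.shape[1]} columns, basis expects {total_p}"
        )
    return np.hstack(
        [X[:, g] @ V for g, V in zip(basis.groups, basis.axes)]
    )


@dataclass
class PCRSGLModel:
    """SGL fitted on group-wise PC scores, with back-projected coefficients."""

    basis: GroupPCBasis
    score_model: SGLModel
    coefficients: np.ndarray  # beta = V theta, length P
    intercept: float
    hyperparams: SGLHyperparams
    loss: str

    @property
    def score_coefficients(self) -> np.ndarray:
        return self.score_model.coefficients

    @property
    def fit_record(self):
        return self.score_model.fit_record

    @property
    def groups(self) -> list:
        return self.basis.groups

    @property
    def active_groups_(self) -> np.ndarray:
        return np.array(
            [i for i, g in enumerate(self.basis.groups)
             if np.any(self.coefficients[g] != 0)],
            dtype=int,
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        eta = self.intercept + X @ self.coefficients
        if self.loss == "squared":
            return eta
        return (self.predict_proba(X) >= 0.5).astype(float)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.score_model.predict_proba(transform_to_scores(X, self.basis))


def fit_pcr_sgl(
    X_train: np.ndarray,
    y: np.ndarray,
    hp: SGLHyperparams,
    groups=None,
    loss: str = "squared",
    basis: GroupPCBasis | None = None,
    **fit_kwargs,
) -> PCRSGLModel:
    """Fit the SGL in group-wise score space and back-project.

    The PC basis is fitted on ``X_train`` (pass ``groups``) unless a
    prefitted ``basis`` is supplied (e.g. inside cross-validation, where it
    must come from training rows only).  Score-space groups have sizes r_l
    and (unless overridden through ``hp.group_weights``) weights sqrt(r_l).
    Scores are deliberately not re-standardized: they inherit the variance
    ordering of the singular values, which is the point of the PC
    projection.
    """
    X_train = np.asarray(X_train, dtype=float)
    if basis is None:
        if groups is None:
            raise TypeError("fit_pcr_sgl needs either groups or a basis")
        basis = fit_group_pca(X_train, groups)
    Z = transform_to_scores(X_train, basis)
    score_groups = basis.score_groups()
    model = fit_sgl(Z, y, hp, score_groups, loss=loss, **fit_kwargs)
    beta = np.zeros(sum(len(g) for g in basis.groups))
    for g, V, sg in zip(basis.groups, basis.axes, score_groups):
        beta[g] = V @ model.coefficients[sg]
    return PCRSGLModel(
        basis=basis,
        score_model=model,
        coefficients=beta,
        intercept=model.intercept,
        hyperparams=hp,
        loss=loss,
    )
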