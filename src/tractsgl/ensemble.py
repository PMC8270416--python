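"""Bootstrap-aggregated (bagged) meta-estimation over SGL-family models.

Each of the m constituents is fitted on n_train rows drawn with replacement
from the training set; the ensemble's coefficients, hyperparameters and
predictions are arithmetic means over constituents.  Classification is
aggregated as mean probability (soft vote), matching the probability-level
reporting of the base models; ties at p = 0.5 go to class 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError

__all__ = ["BaggedEnsemble", "fit_bagged", "predict_ensemble"]

_MAX_REDRAWS = 100


@dataclass
class BaggedEnsemble:
    models: list
    resample_indices: list  # per-constituent bootstrap row indices
    seed: int
    loss: str  # "squared" | "logistic"
    coefficients: np.ndarray = field(init=False)
    intercept: float = field(init=False)
    alpha: float = field(init=False)
    lam: float = field(init=False)

    def __post_init__(self):
        if not self.models:
            raise ValueError("empty ensemble")
        self.coefficients = np.mean(
            [m.coefficients for m in self.models], axis=0
        )
        self.intercept = float(np.mean([m.intercept for m in self.models]))
        self.alpha = float(
            np.mean([m.hyperparams.alpha for m in self.models])
        )
        self.lam = float(np.mean([m.hyperparams.lam for m in self.models]))

    @property
    def m(self) -> int:
        return len(self.models)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_ensemble(self, X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.loss != "logistic":
            raise ValueError("predict_proba requires logistic constituents")
        return np.mean([m.predict_proba(X) for m in self.models], axis=0)


def fit_bagged(
    base_fit,
    X: np.ndarray,
    y: np.ndarray,
    m: int = 20,
    seed: int = 0,
    loss: str = "squared",
    resample: bool = True,
) -> BaggedEnsemble:
    """Fit m constituents of ``base_fit(X_boot, y_boot)`` on bootstrap rows.

    Deterministic given ``seed``.  For the logistic loss, a resample that
    contains a single class is redrawn (bounded retries).  ``resample=False``
    forces every constituent onto the identity rows, collapsing the ensemble
    onto the base model (useful for audits).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    models, indices = [], []
    for _ in range(m):
        if resample:
            idx = rng.integers(0, n, size=n)
            if loss == "logistic":
                for _retry in range(_MAX_REDRAWS):
                    if len(np.unique(y[idx])) > 1:
                        break
                    idx = rng.integers(0, n, size=n)
                else:
                    raise ValueError(
                        "could not draw a two-class bootstrap resample"
                    )
        else:
            idx = np.arange(n)
        models.append(base_fit(X[idx], y[idx]))
        indices.append(idx)
    return BaggedEnsemble(
        models=models, resample_indices=indices, seed=seed, loss=loss
    )


def predict_ensemble(ens: BaggedEnsemble, X: np.ndarray) -> np.ndarray:
    """Mean of constituent predictions (regression, on the model scale) or
    thresholded mean probability (classification)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != ens.coefficients.shape[0]:
        raise DimensionError(
            f"X has {X.shape[1]} columns, ensemble expects "
            f"{ens.coefficients.shape[0]}"
        )
    if ens.loss == "squared":
        return np.mean([m.predict(X) for m in ens.models], axis=0)
    return (ens.predict_proba(X) >= 0.5).astype(float)
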