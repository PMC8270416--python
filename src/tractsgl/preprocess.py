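"""Missing-node imputation, train-only z-scoring, and target transforms.

Imputation never crosses a (bundle, metric) group boundary and uses only the
subject's own profile values, so it cannot leak information across subjects
or folds.  Z-scoring statistics are fitted on training rows only and applied
unchanged to held-out data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, DomainError, ImputationError, PolicyError
from .profiles import GroupedFeatureMatrix, PhenotypeTarget

__all__ = [
    "ImputationPolicy",
    "ScalerParams",
    "impute_profiles",
    "fit_scaler",
    "apply_scaler",
    "transform_target",
    "inverse_transform_predictions",
    "harmonization_hook",
]


@dataclass
class ImputationPolicy:
    """How to fill missing nodes within one subject x group profile.

    Interior gaps are always filled by straight-line interpolation on node
    index.  Exterior (leading/trailing) gaps use either linear extrapolation
    from the two nearest observed nodes or constant forward/back-fill.
    """

    exterior: str = "linear"  # "linear" | "constant"
    max_missing_fraction: float = 0.5

    def __post_init__(self):
        if self.exterior not in ("linear", "constant"):
            raise ValueError(f"unknown exterior rule {self.exterior!r}")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")


def _impute_1d(v: np.ndarray, exterior: str) -> np.ndarray:
    """Fill NaNs of one profile; observed values are left untouched."""
    obs = np.flatnonzero(~np.isnan(v))
    nodes = np.arange(v.shape[0], dtype=float)
    out = np.interp(nodes, obs.astype(float), v[obs])  # constant at edges
    if exterior == "linear" and len(obs) >= 2:
        first, last = obs[0], obs[-1]
        if first > 0:
            slope = (v[obs[1]] - v[first]) / (obs[1] - first)
            out[:first] = v[first] + slope * (nodes[:first] - first)
        if last < v.shape[0] - 1:
            slope = (v[last] - v[obs[-2]]) / (last - obs[-2])
            out[last + 1:] = v[last] + slope * (nodes[last + 1:] - last)
    return out


def impute_profiles(
    matrix: GroupedFeatureMatrix, policy: ImputationPolicy | None = None
) -> GroupedFeatureMatrix:
    """Impute all missing node values; idempotent on complete matrices."""
    if policy is None:
        policy = ImputationPolicy()
    X = matrix.values
    if not np.isnan(X).any():
        return matrix
    out = X.copy()
    for ell, g in enumerate(matrix.groups):
        block = out[:, g]
        nan = np.isnan(block)
        if not nan.any():
            continue
        frac = nan.mean(axis=1)
        bad = np.flatnonzero(frac == 1.0)
        if bad.size:
            raise ImputationError(
                f"subject {matrix.subject_ids[bad[0]]!r} has all nodes "
                f"missing in group {matrix.group_labels[ell]}"
            )
        over = np.flatnonzero(frac > policy.max_missing_fraction)
        if over.size:
            raise PolicyError(
                f"subject {matrix.subject_ids[over[0]]!r} has missing "
                f"fraction {frac[over[0]]:.2f} > "
                f"{policy.max_missing_fraction} in group "
                f"{matrix.group_labels[ell]}"
            )
        for i in np.flatnonzero(nan.any(axis=1)):
            n_obs = int((~nan[i]).sum())
            if policy.exterior == "linear" and n_obs < 2:
                raise ImputationError(
                    f"subject {matrix.subject_ids[i]!r} has a single "
                    f"observed node in group {matrix.group_labels[ell]}; "
                    "linear extrapolation needs two"
                )
            block[i] = _impute_1d(block[i], policy.exterior)
        out[:, g] = block
    return matrix.with_values(out)


# ---------------------------------------------------------------------------
# Z-scoring
# ---------------------------------------------------------------------------

@dataclass
class ScalerParams:
    """Per-column mean and scale learned from training rows only.

    The population (divide-by-n) variance convention is used; zero-variance
    columns get scale 1 so a constant column becomes all-zero rather than
    failing the fit.
    """

    mean: np.ndarray
    scale: np.ndarray
    n_fitted: int

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if np.any(self.scale <= 0):
            raise ValueError("all scales must be > 0")

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean": self.mean.tolist(),
                "scale": self.scale.tolist(),
                "n_fitted": self.n_fitted,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ScalerParams":
        d = json.loads(text)
        return cls(
            mean=np.asarray(d["mean"]),
            scale=np.asarray(d["scale"]),
            n_fitted=int(d["n_fitted"]),
        )


def fit_scaler(train: GroupedFeatureMatrix | np.ndarray) -> ScalerParams:
    X = train.values if hasattr(train, "values") else np.asarray(train, float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows to fit a scaler")
    if np.isnan(X).any():
        raise ValueError("impute before scaling: training matrix has NaN")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population convention (ddof=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return ScalerParams(mean=mean, scale=sd, n_fitted=X.shape[0])


def apply_scaler(matrix, params: ScalerParams):
    """Apply train-fitted z-scoring; works on a matrix object or ndarray."""
    is_obj = hasattr(matrix, "values") and hasattr(matrix, "with_values")
    X = matrix.values if is_obj else np.asarray(matrix, dtype=float)
    if X.shape[1] != params.mean.shape[0]:
        raise DimensionError(
            f"matrix has {X.shape[1]} columns, scaler expects "
            f"{params.mean.shape[0]}"
        )
    Z = (X - params.mean) / params.scale
    return matrix.with_values(Z) if is_obj else Z


# ---------------------------------------------------------------------------
# Target transform
# ---------------------------------------------------------------------------

def transform_target(y: PhenotypeTarget) -> np.ndarray:
    """Map targets to the model scale (identity or natural log)."""
    if y.transform == "identity":
        return y.values.copy()
    bad = np.flatnonzero(y.values <= 0)
    if bad.size:
        who = (
            [y.subject_ids[i] for i in bad[:5]]
            if y.subject_ids
            else bad[:5].tolist()
        )
        raise DomainError(
            f"log transform requires positive targets; offending "
            f"subject(s): {who}"
        )
    return np.log(y.values)


def inverse_transform_predictions(
    v: np.ndarray, transform: str = "identity"
) -> np.ndarray:
    """Map model-scale predictions back to the original target scale."""
    v = np.asarray(v, dtype=float)
    if transform == "identity":
        return v.copy()
    if transform == "log":
        return np.exp(v)
    raise ValueError(f"unknown transform {transform!r}")


def harmonization_hook(matrix, harmonizer=None):
    """Hook point between imputation and scaling for site harmonization.

    The package assumes single-site or already-harmonized input; pass a
    callable to insert an external harmonizer, otherwise identity.
    """
    return matrix if harmonizer is None else harmonizer(matrix)
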