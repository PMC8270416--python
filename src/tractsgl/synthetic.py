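"""Synthetic tract-profile datasets with known ground truth.

The generator emulates the structure of real tractometry data: B bundles x
M metrics x N nodes per subject, within-bundle profiles that are smooth
along the node axis (a per-subject group-level latent plus stationary AR(1)
node noise with lag-1 autocorrelation rho), a group-sparse linear signal
concentrated in contiguous node runs (mirroring the localized bundle
segments seen in real coefficient profiles), Gaussian target noise or
Bernoulli labels, an optional log-scale target, and optional missing nodes.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import SpecError
from .profiles import (
    DEFAULT_BUNDLES,
    GroupedFeatureMatrix,
    PhenotypeTarget,
    TractProfileTable,
)

__all__ = [
    "SyntheticProfileSpec",
    "SyntheticDataset",
    "generate_profiles",
    "matrix_from_dataset",
    "inject_missingness",
]


@dataclass
class SyntheticProfileSpec:
    """Study conditions for one synthetic dataset.

    effect_size is sd(X beta) / noise_sd for continuous targets (the sd of
    the linear predictor for binary targets, whose noise is intrinsic to the
    Bernoulli draw); when noise_sd is 0 the linear predictor is scaled to
    unit sd instead.
    """

    n_subjects: int = 48
    n_bundles: int = 18
    n_metrics: int = 2
    n_nodes: int = 100
    n_active_groups: int = 2
    within_group_active_fraction: float = 0.5
    rho: float = 0.5  # lag-1 autocorrelation of node noise
    effect_size: float = 2.0
    noise_sd: float = 1.0
    task: str = "continuous"  # "continuous" | "binary"
    target_transform: str = "identity"  # "identity" | "log"
    missing_rate: float = 0.0
    missing_pattern: str = "random"  # "interior" | "exterior" | "random"
    signal_placement: str = "contiguous"  # "contiguous" | "scattered"
    latent_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        G = self.n_bundles * self.n_metrics
        if self.n_active_groups > G:
            raise SpecError(
                f"n_active_groups {self.n_active_groups} > G = {G}"
            )
        if not 0.0 < self.within_group_active_fraction <= 1.0:
            raise SpecError("within_group_active_fraction must be in (0, 1]")
        if not 0.0 <= self.rho < 1.0:
            raise SpecError("rho must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SpecError("missing_rate must be in [0, 1)")
        if self.task not in ("continuous", "binary"):
            raise SpecError(f"unknown task {self.task!r}")
        if self.target_transform not in ("identity", "log"):
            raise SpecError(f"unknown transform {self.target_transform!r}")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise SpecError("noise_sd and effect_size must be >= 0")

    def bundle_names(self) -> list:
        names = list(DEFAULT_BUNDLES[: self.n_bundles])
        names += [f"BND{i:02d}" for i in range(len(names), self.n_bundles)]
        return names

    def metric_names(self) -> list:
        return [f"metric{j}" for j in range(self.n_metrics)]

    def to_dict(self) -> dict:
        return asdict(self)


class SyntheticDataset(NamedTuple):
    table: TractProfileTable
    target: PhenotypeTarget
    true_beta: np.ndarray
    true_support: np.ndarray  # boolean, per feature; == (true_beta != 0)


def _matrix_layout(spec: SyntheticProfileSpec):
    """Column layout matching assemble_feature_matrix: (bundle, metric)
    combos sorted lexicographically, node fastest."""
    combos = sorted(
        (b, m) for b in spec.bundle_names() for m in spec.metric_names()
    )
    N = spec.n_nodes
    groups = [
        np.arange(i * N, (i + 1) * N, dtype=np.intp)
        for i in range(len(combos))
    ]
    return combos, groups


def _ar1(rng, shape, rho):
    """Stationary unit-variance AR(1) noise along the last axis."""
    eps = rng.standard_normal(shape)
    out = np.empty(shape)
    out[..., 0] = eps[..., 0]
    c = np.sqrt(1.0 - rho * rho)
    for t in range(1, shape[-1]):
        out[..., t] = rho * out[..., t - 1] + c * eps[..., t]
    return out


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def generate_profiles(spec: SyntheticProfileSpec) -> SyntheticDataset:
    """Draw one dataset with group-sparse ground-truth coefficients.

    Features: X[s, (l, t)] = latent[s, l] + AR(rho) noise, so nearby nodes
    co-vary as real tract profiles do.  true_beta is zero outside
    ``n_active_groups`` randomly chosen groups; within an active group the
    nonzero run covers ``within_group_active_fraction`` of the nodes with a
    half-sine amplitude profile and a random sign.
    """
    rng = np.random.default_rng(spec.seed)
    combos, groups = _matrix_layout(spec)
    S, N, G = spec.n_subjects, spec.n_nodes, len(combos)
    P = G * N

    latent = rng.standard_normal((S, G)) * spec.latent_sd
    ar = _ar1(rng, (S, G, N), spec.rho)
    X = (latent[:, :, None] + ar).reshape(S, P)

    beta = np.zeros(P)
    active = np.sort(rng.choice(G, size=spec.n_active_groups, replace=False))
    run = max(1, int(round(spec.within_group_active_fraction * N)))
    for ell in active:
        sign = rng.choice([-1.0, 1.0])
        if spec.signal_placement == "contiguous":
            start = int(rng.integers(0, N - run + 1))
            nodes = np.arange(start, start + run)
        else:
            nodes = np.sort(rng.choice(N, size=run, replace=False))
        bump = np.sin(np.pi * (np.arange(run) + 0.5) / run)
        beta[groups[ell][nodes]] = sign * bump

    eta = X @ beta
    eta = eta - eta.mean()
    sd = eta.std()
    if spec.n_active_groups > 0 and sd > 0:
        unit = spec.noise_sd if spec.noise_sd > 0 else 1.0
        scale = spec.effect_size * unit / sd
        eta *= scale
        beta *= scale
    if spec.task == "continuous":
        y = eta + rng.normal(0.0, spec.noise_sd, size=S)
        if spec.target_transform == "log":
            y = np.exp(y)
        kind = "continuous"
    else:
        y = rng.binomial(1, _sigmoid(eta)).astype(float)
        kind = "binary"

    subject_ids = [f"sub-{i:04d}" for i in range(S)]
    table = _table_from_matrix(X, combos, N, subject_ids)
    if spec.missing_rate > 0:
        table = inject_missingness(
            table, spec.missing_rate, spec.missing_pattern,
            seed=int(rng.integers(2**31)),
        )
    target = PhenotypeTarget(
        values=y,
        kind=kind,
        transform=spec.target_transform,
        subject_ids=subject_ids,
    )
    return SyntheticDataset(
        table=table, target=target, true_beta=beta, true_support=beta != 0
    )


def _table_from_matrix(X, combos, N, subject_ids) -> TractProfileTable:
    S = X.shape[0]
    G = len(combos)
    rows = {
        "subjectID": np.repeat(subject_ids, G * N),
        "tractID": np.tile(np.repeat([b for b, _ in combos], N), S),
        "metric": np.tile(np.repeat([m for _, m in combos], N), S),
        "nodeID": np.tile(np.arange(N), S * G),
        "value": X.reshape(-1),
    }
    return TractProfileTable(data=pd.DataFrame(rows), n_nodes=N)


def matrix_from_dataset(
    ds: SyntheticDataset, spec: SyntheticProfileSpec
) -> GroupedFeatureMatrix:
    """Assemble the design matrix directly (bypasses the pivot for speed);
    identical layout to :func:`tractsgl.profiles.assemble_feature_matrix`."""
    combos, groups = _matrix_layout(spec)
    df = ds.table.data.sort_values(
        ["subjectID", "tractID", "metric", "nodeID"], kind="mergesort"
    )
    values = df["value"].to_numpy(dtype=float).reshape(
        spec.n_subjects, len(combos) * spec.n_nodes
    )
    meta = pd.DataFrame(
        [(b, m, n) for b, m in combos for n in range(spec.n_nodes)],
        columns=["tractID", "metric", "nodeID"],
    )
    return GroupedFeatureMatrix(
        values=values,
        groups=groups,
        column_meta=meta,
        subject_ids=sorted(df["subjectID"].unique()),
        group_labels=combos,
    )


def inject_missingness(
    table: TractProfileTable,
    missing_rate: float,
    pattern: str = "random",
    seed: int = 0,
) -> TractProfileTable:
    """Mask a fraction of node values per subject x group.

    Patterns: ``interior`` never touches the first or last node;
    ``exterior`` masks runs at the profile ends; ``random`` masks anywhere.
    An entire subject x group profile is never fully masked.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise SpecError("missing_rate must be in [0, 1)")
    if pattern not in ("interior", "exterior", "random"):
        raise SpecError(f"unknown missingness pattern {pattern!r}")
    if missing_rate == 0.0:
        return table
    rng = np.random.default_rng(seed)
    N = table.n_nodes
    k = int(round(missing_rate * N))
    if k >= N:
        raise SpecError("missing_rate would mask entire profiles")
    if k == 0:
        return table
    if pattern == "interior" and k > N - 2:
        raise SpecError("interior masking must keep both end nodes")

    df = table.data.copy()
    values = df["value"].to_numpy(dtype=float).copy()
    for _, idx in df.groupby(
        ["subjectID", "tractID", "metric"], sort=True
    ).indices.items():
        idx = np.asarray(idx)
        node_of = df["nodeID"].to_numpy()[idx]
        order = np.argsort(node_of)
        idx = idx[order]
        n_here = len(idx)
        kk = min(k, n_here - 1)  # never mask all
        if pattern == "interior":
            pool = np.arange(1, n_here - 1)
            kk = min(kk, len(pool))
            masked = rng.choice(pool, size=kk, replace=False)
        elif pattern == "exterior":
            head = int(rng.integers(0, kk + 1))
            tail = kk - head
            masked = np.concatenate(
                [np.arange(head), np.arange(n_here - tail, n_here)]
            )
        else:
            masked = rng.choice(n_here, size=kk, replace=False)
        values[idx[masked]] = np.nan
    df["value"] = values
    return TractProfileTable(data=df, n_nodes=N)
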