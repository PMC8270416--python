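import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles helper module

from tractsgl import (
    SyntheticProfileSpec,
    generate_profiles,
    matrix_from_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_regression():
    """Small grouped regression dataset with a known 2-group signal."""
    spec = SyntheticProfileSpec(
        n_subjects=60,
        n_bundles=5,
        n_metrics=2,
        n_nodes=10,
        n_active_groups=2,
        within_group_active_fraction=1.0,
        effect_size=3.0,
        noise_sd=1.0,
        seed=11,
    )
    ds = generate_profiles(spec)
    return spec, ds, matrix_from_dataset(ds, spec)


@pytest.fixture(scope="session")
def small_classification():
    """Balanced binary dataset with one strongly informative group."""
    spec = SyntheticProfileSpec(
        n_subjects=60,
        n_bundles=4,
        n_metrics=1,
        n_nodes=10,
        n_active_groups=1,
        within_group_active_fraction=1.0,
        effect_size=3.0,
        task="binary",
        seed=21,
    )
    ds = generate_profiles(spec)
    return spec, ds, matrix_from_dataset(ds, spec)


@pytest.fixture
def random_grouped_problem(rng):
    """Factory for random (X, y, groups) instances."""

    def make(n=40, sizes=(6, 6, 6, 6), noise=0.5, seed=None, loss="squared"):
        r = np.random.default_rng(seed) if seed is not None else rng
        p = sum(sizes)
        X = r.standard_normal((n, p))
        beta = np.zeros(p)
        beta[: sizes[0]] = r.standard_normal(sizes[0])
        eta = X @ beta
        groups = []
        start = 0
        for s in sizes:
            groups.append(np.arange(start, start + s))
            start += s
        if loss == "logistic":
            y = (r.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        else:
            y = eta + noise * r.standard_normal(n) + 1.5
        return X, y, groups

    return make
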