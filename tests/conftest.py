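import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from regwire.dataset import ExpressionDataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_dataset(values, groups=None, series=None, group_levels=None):
    """Small helper: build a dataset from a raw matrix."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    if groups is None:
        half = n_samples // 2
        groups = ["A"] * half + ["B"] * (n_samples - half)
    if series is None:
        series = [1] * n_samples
    ids = [f"P{i+1}" for i in range(n_probes)]
    samples = [f"s{i+1}" for i in range(n_samples)]
    design = pd.DataFrame(
        {"group": groups, "series": series},
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionDataset(
        values=pd.DataFrame(values, index=ids, columns=samples),
        design=design,
        group_levels=group_levels,
    )


def rows_with_correlations(corr, n_samples=8, rng=None):
    """Construct rows whose sample Pearson correlations equal ``corr`` exactly.

    Orthonormalizes random centered rows, then mixes them with the Cholesky
    factor of the target correlation matrix.
    """
    corr = np.asarray(corr, dtype=float)
    k = corr.shape[0]
    rng = rng or np.random.default_rng(1234)
    raw = rng.standard_normal((k, n_samples))
    raw -= raw.mean(axis=1, keepdims=True)
    # Gram-Schmidt on centered rows
    basis = []
    for row in raw:
        for b in basis:
            row = row - (row @ b) * b
        basis.append(row / np.linalg.norm(row))
    basis = np.array(basis)
    L = np.linalg.cholesky(corr)
    return L @ basis


@pytest.fixture
def toy_dataset():
    rng = np.random.default_rng(7)
    return make_dataset(rng.normal(7, 1, (10, 8)))
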