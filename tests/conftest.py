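import numpy as np
import pytest

from sgccapipe import CovariateTable, MultiViewDataset, ViewMatrix


def make_dataset(matrices, names=None, covariates=None, standardized=True):
    """Build a MultiViewDataset from raw arrays (dummy covariates by default)."""
    n = matrices[0].shape[0]
    ids = [f"s{i:04d}" for i in range(n)]
    names = names or [f"view{j}" for j in range(len(matrices))]
    views = []
    for name, x in zip(names, matrices):
        x = np.asarray(x, dtype=float)
        if standardized:
            x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        views.append(
            ViewMatrix(name, ids, [f"{name}_{i}" for i in range(x.shape[1])], x)
        )
    if covariates is None:
        rng = np.random.default_rng(abs(hash(tuple(names))) % 2**31)
        covariates = CovariateTable(
            ids,
            rng.uniform(18, 28, n),
            rng.integers(0, 2, n).astype(float),
            np.array([f"site{1 + i % 2}" for i in range(n)], dtype=object),
        )
    return MultiViewDataset(views=views, covariates=covariates)


def random_dataset(seed, n, ps, names=None):
    rng = np.random.default_rng(seed)
    return make_dataset([rng.standard_normal((n, p)) for p in ps], names=names)


@pytest.fixture
def two_view_dataset():
    return random_dataset(0, 100, [5, 4])


@pytest.fixture
def three_view_dataset():
    return random_dataset(1, 120, [10, 9, 8])
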