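import numpy as np
import pytest

from plsmc.data_io import ExpressionDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_dataset(rng):
    """10 genes x 6 samples with a continuous phenotype."""
    values = rng.normal(8.0, 1.0, (10, 6))
    y = rng.uniform(0, 100, 6)
    return ExpressionDataset(
        [f"g{i}" for i in range(10)], [f"s{j}" for j in range(6)], values, y
    )


@pytest.fixture
def planted_problem(rng):
    """n=40 samples, one gene exactly tracking y among 99 noise genes."""
    n, p = 40, 100
    y = rng.uniform(0, 100, n)
    X = rng.normal(size=(n, p))
    X[:, 0] = (y - y.mean()) / y.std()
    return X, y, 0
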