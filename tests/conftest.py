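import numpy as np
import pytest

from qsarmlr import CompoundRecord, QsarDataset
from qsarmlr import data as fixtures


def make_dataset(X, y=None, names=None, ids=None):
    """Build a QsarDataset from plain arrays (test helper)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    names = names or [f"x{j + 1}" for j in range(p)]
    ids = ids or [f"c{i + 1}" for i in range(n)]
    records = [
        CompoundRecord(
            id=ids[i],
            descriptors={nm: float(X[i, j]) for j, nm in enumerate(names)},
            activity=None if y is None else float(y[i]),
        )
        for i in range(n)
    ]
    return QsarDataset(records, names)


@pytest.fixture(scope="session")
def table3():
    """The packaged 26-compound reference dataset."""
    return fixtures.load_table3()


@pytest.fixture(scope="session")
def table5():
    return fixtures.load_table5()


@pytest.fixture(scope="session")
def model2():
    """The packaged best reference equation (4 descriptors)."""
    return fixtures.model_equation(2)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
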