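import numpy as np
import pytest

import blocknmtf as b


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_exact():
    """8x6 matrix that factorises exactly at rank (2, 2)."""
    return b.make_exact(8, 6, 2, 2, seed=11)


@pytest.fixture
def random_instance(rng):
    """Random dense matrix with factors of consistent shape (not a fit)."""
    X = b.DataMatrix(rng.random((6, 4)))
    f = b.FactorTriple(rng.random((6, 2)), rng.random((2, 2)), rng.random((4, 2)))
    return X, f
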