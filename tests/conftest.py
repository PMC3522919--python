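import numpy as np
import pytest

import tsklm


@pytest.fixture(scope="session")
def treadmill():
    """Default synthetic treadmill dataset (N = 76, rho = 0.892)."""
    ds = tsklm.generate(tsklm.activity_profile("treadmill"), seed=11)
    X = ds.table[["hr", "mi"]].to_numpy()
    y = ds.table["ee"].to_numpy()
    return ds, X, y


@pytest.fixture(scope="session")
def trained_model(treadmill):
    _, X, y = treadmill
    return tsklm.train(X, y, p=4, c=3, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
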