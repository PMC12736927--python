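import numpy as np
import pandas as pd
import pytest

from aquaspec import SpectraSet


def make_meta(n, **overrides):
    """A valid metadata frame with n distinct measurement keys."""
    base = dict(
        cultivar=["A"] * n,
        treatment=["stress"] * n,
        plant_id=list(range(1, n + 1)),
        leaf=["first"] * n,
        day=[0] * n,
        replicate=[1] * n,
    )
    base.update(overrides)
    return pd.DataFrame(base)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_set(rng):
    """3 measurements x 10 channels with distinct plant ids."""
    wl = np.linspace(1000.0, 1090.0, 10)
    mat = rng.normal(0.5, 0.1, size=(3, 10))
    return SpectraSet(wl, mat, make_meta(3))


@pytest.fixture
def uniform_grid():
    return np.linspace(908.0, 1676.0, 125)
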