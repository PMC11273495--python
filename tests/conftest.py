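import numpy as np
import pytest

from hgtmda import data_io, synthetic


@pytest.fixture(scope="session")
def default_fixture():
    """The standard synthetic benchmark (100 miRNAs x 60 diseases, rank 5)."""
    return synthetic.generate(synthetic.SyntheticSpec())


@pytest.fixture(scope="session")
def small_fixture():
    """A small, fast fixture for training-loop tests."""
    spec = synthetic.SyntheticSpec(km=30, kd=20, rank=3, seed=11)
    return synthetic.generate(spec)


@pytest.fixture(scope="session")
def small_split(small_fixture):
    ds, mv, dv, gt = small_fixture
    ds = data_io.sample_negatives(ds, seed=3)
    split = data_io.make_splits(ds, 0.2, 5, seed=3)
    return ds, mv, dv, split


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
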