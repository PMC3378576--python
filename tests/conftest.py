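import logging

import numpy as np
import pytest

from structclass import SimulationConfig, simulate_dataset
from structclass.io import PSSM


@pytest.fixture(autouse=True)
def _quiet_warnings(caplog):
    # short-domain feature warnings and ridge-fallback logs are expected
    # on tiny fixtures; keep test output readable
    logging.getLogger("structclass").setLevel(logging.ERROR)
    yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_pssm(rng, L, lo=-8, hi=10):
    seq = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=L))
    scores = rng.integers(lo, hi + 1, size=(L, 20))
    return PSSM(seq, scores)


@pytest.fixture(scope="session")
def tiny_split():
    """A small but fully-trainable synthetic train/test split."""
    cfg = SimulationConfig(n_per_class=15, length_range=(40, 90), seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_train(tiny_split):
    return tiny_split[0]


@pytest.fixture(scope="session")
def tiny_test(tiny_split):
    return tiny_split[1]
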