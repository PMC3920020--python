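import numpy as np
import pytest

from mirloom.precursor import fit_mfe_regression
from mirloom.synthetic import SimulationConfig, mfe_training_table, simulate


@pytest.fixture(scope="session")
def mfe_regression():
    """MFE-vs-length regression trained on designed hairpins (builtin backend)."""
    return fit_mfe_regression(mfe_training_table(20, seed=101))


@pytest.fixture(scope="session")
def dataset():
    """One noiseless synthetic dataset shared across tests."""
    return simulate(SimulationConfig(seed=11, substitution_rate=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
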