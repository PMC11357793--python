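import numpy as np
import pytest

from cspower import ScenarioConfig, simulate_dataset
from cspower.params import build_synthetic_paramset

DEFAULT_ALPHA3 = (4.5, 9.0, 16.5)


@pytest.fixture(scope="session")
def small_params():
    """A small three-cell parameter set on the packaged default regime."""
    return build_synthetic_paramset(400, 3, DEFAULT_ALPHA3, seed=11)


@pytest.fixture(scope="session")
def null_dataset(small_params):
    """One null (effect size 0) dataset at n=50/group."""
    sc = ScenarioConfig(n_per_group=50, effect_size=0.0, n_genes=400, seed=21)
    return simulate_dataset(small_params, sc)


@pytest.fixture(scope="session")
def signal_dataset(small_params):
    """One dataset with a strong effect (lfc=1) at n=50/group."""
    sc = ScenarioConfig(n_per_group=50, effect_size=1.0, n_genes=400, seed=22)
    return simulate_dataset(small_params, sc)


@pytest.fixture()
def rng():
    return np.random.default_rng(2718)
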