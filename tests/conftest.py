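import numpy as np
import pytest

from ibag.engine import McmcConfig
from ibag.simulation import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_sim():
    """Small continuous-outcome replicate with strong signal, shared read-only."""
    cfg = SimConfig(n=60, k=12, j=6, rho=-0.6, group_size=2, seed=7)
    ds, truth = simulate_dataset(cfg, 0)
    return ds, truth


@pytest.fixture()
def fast_mcmc():
    return McmcConfig(iterations=300, burnin=100, thin=2, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
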