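import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pairgp import GPConfig, HyperPriors, SimConfig, TimeSeries, simulate

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def priors():
    return HyperPriors()


@pytest.fixture
def gpcfg():
    return GPConfig()


@pytest.fixture
def toy_series(rng):
    t = np.sort(rng.uniform(0.0, 100.0, 7))
    x = rng.normal(0.0, 1.0, 7)
    return TimeSeries(t, x)


@pytest.fixture(scope="session")
def small_sim():
    """Small heterogeneous dataset shared across integration tests."""
    cfg = SimConfig(
        n_pairs=3,
        n_genes=24,
        probesets_min=1,
        probesets_max=2,
        samples_min=6,
        samples_max=8,
        frac_de_genes=0.25,
        activation_prob=0.6,
        n_random_pathways=4,
        pathway_size=6,
        n_planted_pathways=1,
        planted_size=6,
        planted_activation=0.8,
        seed=7,
    )
    return simulate(cfg)
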