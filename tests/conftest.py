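import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from agecorr.synthetic import SimulationConfig, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reduced_cohort():
    """One scaled-down simulated cohort shared across tests (fixed seed)."""
    return simulate_cohort(SimulationConfig.reduced(seed=11))


@pytest.fixture(scope="session")
def tiny_config():
    """A very small cohort configuration for fast per-test simulation."""
    return SimulationConfig(
        n_tumor=20,
        n_normal=8,
        n_mirna=12,
        n_gene=30,
        n_planted_pos=3,
        n_planted_neg=2,
        n_tumor_only=2,
        targets_per_mirna=6.0,
        seed=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
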