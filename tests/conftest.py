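import numpy as np
import pytest

from replipower.assoc_core import AssociationSummary
from replipower.prior_estimation import fit_prior_arrays
from replipower.simulate import SimulationConfig, simulate_two_stage


@pytest.fixture(scope="session")
def benchmark_config() -> SimulationConfig:
    """The standard two-stage benchmark design used across the experiments."""
    return SimulationConfig()


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Down-scaled design for cheap end-to-end checks."""
    return SimulationConfig(m=2000)


@pytest.fixture(scope="session")
def sim_data(benchmark_config):
    """One simulated two-stage dataset under the benchmark design."""
    return simulate_two_stage(benchmark_config, rng_seed=1)


@pytest.fixture(scope="session")
def sim_prior(sim_data):
    mu, sigma, z = sim_data.primary_stats()
    return fit_prior_arrays(z, sigma)


def make_summary(mu_hat: float, sigma: float, snp_id: str = "snp") -> AssociationSummary:
    return AssociationSummary.from_estimate(snp_id, mu_hat, sigma)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
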