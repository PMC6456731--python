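import numpy as np
import pytest

from dmclust import SamplerConfig, SimulationConfig, run_mcmc, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """Well-separated three-cluster cohort at desk scale."""
    cfg = SimulationConfig(G=50, K=3, L=3, cells_per_individual=80,
                           sigma2=0.05, separation=2.0,
                           depth_model=("fixed", 500), seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_result(small_sim):
    """One short sampler run on the small cohort, reused across tests."""
    cfg = SamplerConfig(K=3, n_iter=150, burn_in=50, seed=5)
    return run_mcmc(small_sim.dataset, cfg)
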