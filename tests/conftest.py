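import numpy as np
import pytest

from mnlnet import netsim
from mnlnet.car import CarParams, build_precision, log_network_likelihood, profile_sigma2


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_instance(rng):
    """Random K=6, N=20 data with a random network — generic likelihood input."""
    W = netsim.generate_solution_network(6, p_extra=0.3, seed=1)
    B = rng.standard_normal((20, 6))
    return B, W


def chain_network(K: int) -> np.ndarray:
    W = np.zeros((K, K))
    idx = np.arange(K - 1)
    W[idx, idx + 1] = W[idx + 1, idx] = 1.0
    return W


def profiled_loglik(B, W, gamma=0.9) -> float:
    """Log-likelihood at the closed-form sigma2 maximiser (test helper)."""
    s2 = profile_sigma2(B, W, gamma)
    return log_network_likelihood(B, W, CarParams(gamma=gamma, sigma2=s2))


@pytest.fixture(scope="session")
def recovery_study():
    """Shared full-scale recovery run: K=68, both configurations, 6 replicates.

    Session-scoped because the 24 network fits dominate the suite's runtime;
    several tests read different summaries off the same table.
    """
    study = netsim.StudyConfig(
        K=68,
        sample_sizes=(100, 250, 500, 1000),
        replicates=6,
        seed=20260926,
    )
    return netsim.run_simulation_study(study)
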