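import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from samestat import SimulationConfig, run_experiment

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# One master seed for every stochastic check in the suite.
MASTER_SEED = 20240613


@pytest.fixture
def rng():
    return np.random.default_rng(MASTER_SEED)


# Session-scoped simulation cells shared across calibration/power checks so
# the expensive replicate loops run once.


@pytest.fixture(scope="session")
def null_mutation_experiment():
    """1000 null replicates of the exome-design mutation-level cell."""
    cfg = SimulationConfig(rho1=0.05, beta=0.0, seed=MASTER_SEED)
    return run_experiment(cfg, reps=1000)


@pytest.fixture(scope="session")
def null_gene_experiment():
    """1000 null replicates of the gene-level cell (p=10, rho1_g=0.10)."""
    cfg = SimulationConfig(level="gene", rho1=0.10, beta=0.0,
                           seed=MASTER_SEED + 1)
    return run_experiment(cfg, reps=1000)


@pytest.fixture(scope="session")
def power_mutation_cell():
    """500 replicates at beta=0.6, rho1=0.10 (continuous outcome)."""
    cfg = SimulationConfig(rho1=0.10, beta=0.6, seed=MASTER_SEED + 2)
    return run_experiment(cfg, reps=500)


@pytest.fixture(scope="session")
def power_gene_cell():
    """500 replicates of the matched-frequency gene-level power cell."""
    cfg = SimulationConfig(level="gene", rho1=0.10, beta=0.6,
                           seed=MASTER_SEED + 2)
    return run_experiment(cfg, reps=500)
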