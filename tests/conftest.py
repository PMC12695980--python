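import numpy as np
import pytest

from fedgwas import PipelineConfig, SimulationConfig, simulate_study
from fedgwas.config import GridConfig


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    """A desk-scale study exercising every pipeline stage."""
    return PipelineConfig(
        simulation=SimulationConfig(
            n_samples=300,
            n_snps=120,
            n_covariates=2,
            n_nodes=3,
            n_causal=5,
            heritability=0.4,
            seed=7,
        ),
        grid=GridConfig(n_folds=3, n_penalties=3, block_size=40),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config.simulation)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
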