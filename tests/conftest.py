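import numpy as np
import pytest

from bayesgs.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small but non-trivial dataset for fast sampler/pipeline checks."""
    return simulate_dataset(SimulationConfig(
        n_founders=60, n_generations=2, family_size=5, n_validation_families=20,
        n_snp=60, n_qtl=8, max_qtl_variance_share=0.2, seed=42,
    ))


@pytest.fixture(scope="session")
def default_dataset():
    """Full-scale dataset under the study's default generator settings."""
    return simulate_dataset(SimulationConfig(seed=123))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
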