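import numpy as np
import pytest

from rarecnv.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast cohort: everything the pipeline touches, at toy scale."""
    return SimulationConfig(
        seed=7,
        n_cases=40,
        n_controls=80,
        n_chromosomes=3,
        chromosome_length_bp=30_000_000,
        mean_calls_per_sample=12.0,
        polymorphic_pool_size=5,
        polymorphic_carrier_rate=0.3,
        n_genes=120,
        n_snps=2000,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
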