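import numpy as np
import pytest

from debiasfs import MOOConfig, SyntheticSpec, generate_biased_dataset


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Desk-scale generator spec: 3 diagnoses, 3 sites, 32 dims."""
    return SyntheticSpec(
        n_per_diagnosis_per_split=(24, 8, 8),
        diagnoses=("dA", "dB", "dC"),
        sites=("h1", "h2", "h3"),
        d_class=6,
        d_site=6,
        d_confounded=4,
        d_noise=16,
        class_effect=2.0,
        site_effect=2.0,
        confounding=0.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_biased_dataset(small_spec)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    return small_dataset[0]


@pytest.fixture(scope="session")
def small_truth(small_dataset):
    return small_dataset[1]


@pytest.fixture
def fast_config() -> MOOConfig:
    """A few generations on the small table: quick but non-trivial."""
    return MOOConfig(
        population_size=16,
        fitness_budget=16 * 8,
        reference_divisions=6,
        seed=11,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
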