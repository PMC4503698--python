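import numpy as np
import pytest

from occumix import (
    GeneratorConfig,
    MCMCConfig,
    default_true_parameters,
    simulate_dataset,
    simulate_detection_study,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)


@pytest.fixture
def true_params():
    return default_true_parameters()


@pytest.fixture
def small_config():
    """A scaled-down study design for fast simulation-based tests."""
    return GeneratorConfig(
        n_set1=20, n_set2=12, n_set3_restored=5, n_set3_unrestored=5,
        n_detection_sites=10,
    )


@pytest.fixture
def small_dataset(true_params, small_config, rng):
    dataset, latents = simulate_dataset(true_params, small_config, rng)
    dataset.detection.extend(
        simulate_detection_study(true_params, small_config, rng)
    )
    return dataset, latents


@pytest.fixture
def fast_mcmc():
    return MCMCConfig(n_chains=2, n_burnin=300, n_samples=1200, seed=11)
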