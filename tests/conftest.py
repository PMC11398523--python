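import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bgeeval.synthetic import (CohortConfig, simulate_array_genotypes,
                               simulate_lowpass_dosages, simulate_truth)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_samples=150, n_sites=800, seed=42)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_truth(small_config)


@pytest.fixture(scope="session")
def small_dosages(small_truth, small_config):
    return simulate_lowpass_dosages(small_truth, small_config)


@pytest.fixture(scope="session")
def small_array(small_truth, small_config):
    return simulate_array_genotypes(small_truth, small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
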