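import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import paretosig as ps

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy():
    return ps.make_toy_fixture()


@pytest.fixture(scope="session")
def toy_network(toy):
    return ps.PPINetwork(toy.ppi, toy.target)


@pytest.fixture(scope="session")
def small_dataset():
    """Modest synthetic dataset shared by pipeline-level tests."""
    cfg = ps.SyntheticConfig(
        n_sites=120, n_train_samples=14, n_validation_samples=4,
        n_informative=3, n_proteins=80, network_edges=200, n_decoy_edges=40,
        noise_sd=0.2, seed=7,
    )
    return ps.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_run_config():
    return ps.RunConfig(population_size=24, stagnation_generations=5,
                        max_generations=40, n_clusters=2, seed=7)


@pytest.fixture(scope="session")
def small_result(small_dataset, small_run_config):
    train, tl, val, vl, ppi, _truth = small_dataset
    return ps.run_pipeline(train, tl, ppi, "TARGET", validation=val,
                           validation_labels=vl, config=small_run_config)
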