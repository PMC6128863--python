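import pytest
from hypothesis import HealthCheck, settings

import flavnet as fv

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset shared by read-only tests."""
    config = fv.SimConfig(
        n_genes=600, n_planted_deu_per_phase=10, go_terms=60, seed=7
    )
    catalog = fv.generate_catalog(config)
    cm, truth = fv.simulate_counts(catalog, config)
    return config, catalog, cm, truth


@pytest.fixture(scope="session")
def small_comparisons(small_dataset):
    _, _, cm, _ = small_dataset
    return fv.compare_all_phases(cm)
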