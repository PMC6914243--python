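import pytest

from trialcea.costing import build_cost_panel
from trialcea.outcomes import derive_outcomes
from trialcea.synthetic import GeneratorConfig, apply_missingness, generate_trial


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A quick-to-generate two-arm configuration."""
    return GeneratorConfig(n_per_arm=(20, 18), seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_trial(small_config)


@pytest.fixture(scope="session")
def small_dataset_missing(small_config, small_dataset):
    return apply_missingness(small_dataset, small_config)


@pytest.fixture(scope="session")
def small_panels(small_dataset_missing):
    outcomes = derive_outcomes(small_dataset_missing)
    costs = build_cost_panel(small_dataset_missing)
    return outcomes, costs


@pytest.fixture(scope="session")
def default_dataset():
    """Complete (no dropout) dataset at the published arm sizes."""
    cfg = GeneratorConfig(seed=5)
    return generate_trial(cfg)


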