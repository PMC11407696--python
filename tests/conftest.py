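import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from memddg.synthetic import PlantedDatasetSpec, planted_dataset


@pytest.fixture(scope="session")
def planted800():
    """The planted-signal study dataset: n=800, 5 informative Row-PSSM
    features, noise SD 0.3 kcal/mol."""
    return planted_dataset(PlantedDatasetSpec(seed=20240901))


@pytest.fixture(scope="session")
def planted_small():
    """A quick planted dataset for plumbing tests."""
    return planted_dataset(PlantedDatasetSpec(n_records=40, seed=7))


#: compact hyperparameters for fast protocol tests
FAST_HP = {
    "n_estimators": 60,
    "max_depth": 3,
    "learning_rate": 0.2,
    "subsample": 0.9,
    "colsample_bytree": 0.9,
    "reg_alpha": 0.0,
    "reg_lambda": 1.0,
    "min_child_weight": 1,
}


@pytest.fixture
def fast_hp():
    return dict(FAST_HP)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
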