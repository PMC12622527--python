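import numpy as np
import pytest

import ibvs
from ibvs import SyntheticSpec, TrainingConfig


@pytest.fixture(scope="session")
def desk_config():
    """Small search budget shared by every training-dependent test."""
    return TrainingConfig.desk(seed=42, search_trials=5,
                               max_rounds_search=200, max_rounds_final=400)


@pytest.fixture(scope="session")
def planted_libraries():
    """Train/test screens with a 2-SD shift planted on f0..f4."""
    train = ibvs.gen_screening_library(SyntheticSpec(seed=1, effect_size=2.0))
    test = ibvs.gen_screening_library(SyntheticSpec(seed=2, effect_size=2.0))
    return train, test


@pytest.fixture(scope="session")
def planted_model(planted_libraries, desk_config):
    train, _ = planted_libraries
    return ibvs.fit_screen_scorer(train, desk_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
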