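import numpy as np
import pandas as pd
import pytest

from footstrike import (
    EventConfig,
    GaitSimConfig,
    build_feature_table,
    generate_dataset,
)
from footstrike.simulate import noiseless


@pytest.fixture(scope="session")
def sim_cfg() -> GaitSimConfig:
    return GaitSimConfig(seed=42)


@pytest.fixture(scope="session")
def quiet_cfg(sim_cfg) -> GaitSimConfig:
    return noiseless(sim_cfg)


@pytest.fixture(scope="session")
def feature_table(sim_cfg) -> pd.DataFrame:
    """Balanced 240-step feature table shared by the model tests."""
    records = generate_dataset(sim_cfg, n_ff=80, n_mf=80, n_rf=80)
    return build_feature_table(records, EventConfig())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
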