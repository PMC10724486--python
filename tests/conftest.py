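from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from grmkit import GradedResponseModel, load_default_bank
from grmkit.simulate import simulate_study

DATA_DIR = Path(__file__).parent / "data"

# one seed drives the canonical study-shaped fixture used across the suite
STUDY_SEED = 20230928


@pytest.fixture(scope="session")
def default_bank():
    return load_default_bank()


@pytest.fixture(scope="session")
def published_parameters():
    return pd.read_csv(DATA_DIR / "published_item_parameters.csv").set_index("item_id")


@pytest.fixture(scope="session")
def published_information():
    return pd.read_csv(DATA_DIR / "published_item_information.csv").set_index("item_id")


@pytest.fixture(scope="session")
def study_sim():
    """Study-shaped simulation: 1075 persons x 23 items + 3 covariates."""
    responses, theta = simulate_study(seed=STUDY_SEED)
    return responses, theta


@pytest.fixture(scope="session")
def study_calibration(study_sim):
    """One full MML-EM calibration of the study-shaped dataset (shared: ~15 s)."""
    responses, _ = study_sim
    model = GradedResponseModel()
    model.fit(responses)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
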