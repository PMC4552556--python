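"""Shared fixtures: behaviour profiles and a small simulated dataset."""

import warnings

import numpy as np
import pytest

from castoract.features import FEATURE_NAMES, features_table
from castoract.profiles import default_behaviour_profiles
from castoract.simulate import simulate_dataset

# the swimming profile's ODBA target sits below its oscillation floor and
# warns on first calibration; that conflict is tested explicitly elsewhere
warnings.filterwarnings(
    "ignore", message=".*below the oscillation-only floor.*"
)


@pytest.fixture(scope="session")
def profiles():
    return default_behaviour_profiles()


@pytest.fixture(scope="session")
def small_dataset():
    """20 segments per class, enough for structural checks."""
    return simulate_dataset(20, seed=202)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    table = features_table(small_dataset)
    return table[list(FEATURE_NAMES)], table["label"].to_numpy()


@pytest.fixture()
def rng():
    return np.random.default_rng(918273)
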