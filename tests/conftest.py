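import numpy as np
import pytest

from enoserot.synthdata import (
    EnvironmentConfig,
    default_environment,
    simulate_dataset,
)
from enoserot.preprocess import baseline_correct
from enoserot.features import extract_features


def noise_free_env(environment: str = "laboratory") -> EnvironmentConfig:
    """An environment with every stochastic term switched off."""
    return EnvironmentConfig(environment, ambient_offset_scale=0.0, noise_sd=0.0,
                             drift_rate=0.0, amplitude_spread=0.0,
                             concentration_spread=0.0)


@pytest.fixture(scope="session")
def lab_table_small():
    """Feature table of a small default-laboratory dataset (20/class)."""
    env = default_environment("laboratory")
    records = simulate_dataset(20, env, seed=11)
    return extract_features([baseline_correct(r) for r in records])


@pytest.fixture(scope="session")
def storage_table_small():
    """Feature table of a small default-storage dataset (20/class)."""
    env = default_environment("storage")
    records = simulate_dataset(20, env, seed=11)
    return extract_features([baseline_correct(r) for r in records])
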