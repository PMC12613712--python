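import numpy as np
import pandas as pd
import pytest

from cucurgrow import generate_climate, generate_trial, packaged_scenarios


@pytest.fixture(scope="session")
def scenarios():
    return packaged_scenarios()


@pytest.fixture(scope="session")
def baseline_climate():
    """Noise-free climate covering DAT 0..228."""
    return generate_climate(seed=0, t_noise_sd=0.0, solar_noise_sd=0.0)


@pytest.fixture(scope="session")
def climate42():
    return generate_climate(seed=42)


@pytest.fixture(scope="session")
def josho_trial(scenarios, climate42):
    return generate_trial(scenarios["josho"], climate42)


@pytest.fixture
def flat_climate():
    """Constant 20 degC, 10 MJ climate for closed-form checks."""
    n = 240
    return pd.DataFrame(
        {
            "dat": np.arange(n),
            "doy": np.arange(n) % 365 + 1,
            "t_mean": 20.0,
            "solar": 10.0,
            "co2": 420.0,
        }
    )
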