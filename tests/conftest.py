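import numpy as np
import pandas as pd
import pytest

from matalloc import SimulationConfig, generate_colony


@pytest.fixture(scope="session")
def small_colony():
    """A small synthetic colony shared by fit-based tests (~120 obs)."""
    config = SimulationConfig(seed=42, n_mothers=80, n_years=10)
    observations, truth = generate_colony(config)
    return config, observations, truth


@pytest.fixture(scope="session")
def default_colony():
    """A full-size synthetic colony (study dimensions)."""
    config = SimulationConfig(seed=7)
    observations, truth = generate_colony(config)
    return config, observations, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
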