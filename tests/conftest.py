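import numpy as np
import pytest

from stepwise_impact import Grid, default_truth, generate_env_stack


@pytest.fixture(scope="session")
def grid20() -> Grid:
    return Grid(20, 20, cell_size=500.0)


@pytest.fixture(scope="session")
def env20(grid20):
    return generate_env_stack(grid20, seed=7)


@pytest.fixture(scope="session")
def grid100() -> Grid:
    return Grid(100, 100, cell_size=500.0)


@pytest.fixture(scope="session")
def env100(grid100):
    return generate_env_stack(grid100, seed=7)


@pytest.fixture(scope="session")
def beta_true() -> dict:
    return default_truth().beta_true


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
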