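import numpy as np
import pytest

from staghunt import EnergyParams, PayoffScheme, WorldConfig


@pytest.fixture
def small_config() -> WorldConfig:
    """A 20x20 world small enough for exhaustive auditing."""
    return WorldConfig(
        width=20, height=20,
        n_stag_hunters=20, n_hare_hunters=20,
        n_stags=20, n_hares=20,
        energy=EnergyParams(20.0, 20.0, 0.05),
        payoff=PayoffScheme(stag_ratio=3.0),
        reproduction_interval=200,
        t_end=500,
    )


@pytest.fixture
def empty_config() -> WorldConfig:
    return WorldConfig(
        width=10, height=10,
        n_stag_hunters=0, n_hare_hunters=0, n_stags=0, n_hares=0,
        t_end=10,
    )


def make_world(config, seed=0):
    from staghunt.engine import init_world

    return init_world(config, seed)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
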