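import numpy as np
import pytest

from efish.config import ArenaConfig
from efish.policy import PolicyConfig, init_policy


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_arena():
    """A compact arena used across unit tests."""
    return ArenaConfig(width_cm=100.0, height_cm=80.0, n_agents=3, n_patches=2,
                       patch_radius_cm=8.0, patch_capacity=3, max_steps=200,
                       seed=42)


@pytest.fixture
def tiny_policy():
    cfg = PolicyConfig(obs_dim=12, rnn_width=16, head_width=16)
    return init_policy(cfg, seed=7, n_agents=2)
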