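"""Shared fixtures: tiny model configs and a small cached synthetic library."""

import numpy as np
import pytest

from graphscreen.gnn import ModelConfig
from graphscreen.synthetic import SyntheticConfig, generate_library


@pytest.fixture(scope="session")
def tiny_model_config() -> ModelConfig:
    return ModelConfig(hidden_dim=16, n_heads=2, n_layers=2)


@pytest.fixture(scope="session")
def small_library():
    """120-molecule deterministic synthetic library (records, truth)."""
    return generate_library(SyntheticConfig(n_molecules=120, seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
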