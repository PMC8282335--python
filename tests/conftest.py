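"""Shared fixtures: a small simulated population (session-scoped, built
once) and the prepared/normalized arrays and trained smoke network used by
the heavier end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest

from aptrans.dataset import PopulationConfig, build_population, split_dataset
from aptrans.network import NetConfig, init_params
from aptrans.pipeline import prepare_data
from aptrans.training import TrainConfig, train


SMOKE_SEED = 11


@pytest.fixture(scope="session")
def small_population():
    """100 paired samples: 34 drug-free, 30 simple-block (10 levels x 3
    rates), 36 state-dependent."""
    cfg = PopulationConfig(
        n_drug_free=34,
        block_min=0.05, block_max=0.50, block_step=0.05,
        rates_per_level=3,
        n_state_dependent=36,
    )
    return build_population(cfg, seed=SMOKE_SEED)


@pytest.fixture(scope="session")
def smoke_split(small_population):
    return split_dataset(small_population, seed=0)


@pytest.fixture(scope="session")
def smoke_data(smoke_split):
    return prepare_data(smoke_split)


@pytest.fixture(scope="session")
def smoke_training(smoke_data):
    """The scaled-down training run (100 samples, 50 epochs, default
    architecture) shared by the end-to-end tests."""
    params = init_params(NetConfig(), seed=0)
    config = TrainConfig(epochs=50, patience=50, seed=0)
    best, history = train(smoke_data, params, config)
    return best, history


@pytest.fixture(scope="session")
def tiny_net_protocol():
    """Reduced architecture/training protocol for the retraining-heavy
    ablation experiments."""
    net = NetConfig(hidden_size=32, trans_hidden=64, clf_hidden=16, dropout=0.2)
    tr = TrainConfig(epochs=20, patience=20, seed=0)
    return net, tr


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
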