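"""Shared fixtures: a scaled-down trained detection stack on the "easy"
simulated study condition, reused by the heavier end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest

import ptm
from ptm.config import PipelineConfig, RnnConfig


@pytest.fixture(scope="session")
def easy_config() -> PipelineConfig:
    """Pipeline config with a small LSTM so training fits the CI budget."""
    cfg = PipelineConfig()
    cfg.rnn = RnnConfig(hidden=24, epochs=60, seed=0)
    return cfg


@pytest.fixture(scope="session")
def easy_train_meals():
    """Three rendered, annotated meals from the easy preset (training corpus)."""
    easy = ptm.preset("easy")
    return [ptm.simulate_meal(easy, seed=100 + i, render=True) for i in range(3)]


@pytest.fixture(scope="session")
def trained_stack(easy_config, easy_train_meals):
    """(SvmArray, BiteLstm) trained once on the easy training meals."""
    return ptm.train_models(
        [(s.meal, s.labels) for s in easy_train_meals], easy_config, seed=0
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
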