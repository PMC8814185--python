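"""Shared fixtures: small seeded synthetic cohorts and reduced CV configs.

Everything is generated programmatically; sizes are kept small so the whole
suite runs on one CPU in a few minutes.
"""

from __future__ import annotations

import numpy as np
import pytest

from chromadecode.decoder import CVConfig
from chromadecode.preprocess import preprocess_pipeline
from chromadecode.simulate import SimulationConfig, simulate_cohort, simulate_subject


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """2 subjects, 24 sensors, short epoch: fast but structurally complete."""
    return SimulationConfig(
        n_subjects=2,
        n_sensors=24,
        n_trials_per_condition=24,
        epoch_window=(-50.0, 300.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_epochs(tiny_config):
    return simulate_subject(tiny_config, 0)


@pytest.fixture(scope="session")
def tiny_binned(tiny_config):
    return [
        preprocess_pipeline(e, n_per_condition=24, seed=0)
        for e in simulate_cohort(tiny_config)
    ]


@pytest.fixture(scope="session")
def cv_small() -> CVConfig:
    return CVConfig(n_splits=3, trials_per_split=8, n_runs=3, n_selected_sensors=10, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
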