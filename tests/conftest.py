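"""Shared fixtures: cheap simulation configs and pre-computed sessions."""

import numpy as np
import pytest

from spafnirs.pipeline import PipelineConfig, run_model_comparison
from spafnirs.simulate import SimulationConfig, generate_session


def small_config(**overrides) -> SimulationConfig:
    """A fast simulation: few channels, short session, low physiology rate."""
    defaults = dict(
        n_sessions=4,
        n_long_channels=6,
        n_short_channels=2,
        session_duration=360.0,
        n_trials_per_condition=4,
        physio_sample_rate=50.0,
        seed=7,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def quick_config():
    return small_config()


@pytest.fixture(scope="session")
def quick_bundle():
    return generate_session(small_config(), 0)


@pytest.fixture(scope="session")
def quick_comparison():
    """A full six-model comparison on the cheap configuration."""
    cfg = PipelineConfig(seed=7)
    cfg.simulation = small_config()
    return cfg, run_model_comparison(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
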