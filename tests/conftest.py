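"""Shared fixtures: small synthetic sessions reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from srpsearch import (
    BehaviorParams,
    ExperimentConfig,
    SignalParams,
    generate_schedule,
    simulate_behavior,
    synthesize_recording,
)
from srpsearch.study import analyse_session


@pytest.fixture(scope="session")
def small_config() -> ExperimentConfig:
    return ExperimentConfig(n_blocks_per_load=1, n_trials_per_block=6)


@pytest.fixture(scope="session")
def default_session(small_config):
    """One high-load session at default generator parameters."""
    schedule = generate_schedule(small_config, "high", 7)
    outcomes = simulate_behavior(schedule, BehaviorParams(), 8)
    rec = synthesize_recording(schedule, outcomes, SignalParams(), seed=9)
    return schedule, outcomes, rec


@pytest.fixture(scope="session")
def default_analysis(default_session):
    """Full pipeline output for the default session."""
    _, _, rec = default_session
    return analyse_session(rec, participant=0)


@pytest.fixture(scope="session")
def quiet_session(small_config):
    """Session with no noise, blinks or spikes: exact ground-truth checks."""
    params = SignalParams(
        eeg_noise_sd=0.0,
        eeg_white_noise_sd=0.0,
        eog_noise_sd=0.0,
        blink_rate_per_min=0.0,
        eog_spike_rate_per_min=0.0,
        gaze_jitter_px=0.0,
        fixation_scatter_px=0.0,
        pupil_noise_sd=0.0,
        pupil_drift_sd=0.0,
        invalid_sample_prob=0.0,
    )
    config = ExperimentConfig(n_blocks_per_load=1, n_trials_per_block=3)
    schedule = generate_schedule(config, "low", 21)
    outcomes = simulate_behavior(schedule, BehaviorParams(), 22)
    rec = synthesize_recording(schedule, outcomes, params, seed=23)
    return schedule, outcomes, rec


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
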