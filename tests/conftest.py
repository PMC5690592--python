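"""Shared fixtures: simulated recordings reused across the suite."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eitsep.pipeline import process_recording
from eitsep.synth import SimulationParams, make_geometry, simulate_recording

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_recording():
    """One default-condition recording: 45 s breathing + 15 s apnea, 32x32."""
    params = SimulationParams(seed=42)
    movie, flow, truth = simulate_recording(params)
    return params, movie, flow, truth


@pytest.fixture(scope="session")
def processed_default(default_recording):
    _, movie, flow, _ = default_recording
    return process_recording(movie, flow)


@pytest.fixture(scope="session")
def clean_recording():
    """Noise- and jitter-free recording: ground truth holds exactly."""
    params = SimulationParams(seed=7, noise_sd=0.0, rate_jitter_cv=0.0,
                              amp_jitter_cv=0.0)
    movie, flow, truth = simulate_recording(params)
    return params, movie, flow, truth


@pytest.fixture(scope="session")
def processed_clean(clean_recording):
    _, movie, flow, _ = clean_recording
    return process_recording(movie, flow)


@pytest.fixture(scope="session")
def small_recording():
    """Compact 16x16 recording for I/O and pipeline plumbing tests."""
    params = SimulationParams(seed=3, breathing_duration=22.0, apnea_duration=6.0,
                              f_RR=0.318, f_HR=1.43)
    movie, flow, truth = simulate_recording(
        params, make_geometry(16, seed=3), subject_id="S01", position="upright",
        replicate=1, dtype=np.float32)
    return params, movie, flow, truth
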