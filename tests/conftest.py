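import numpy as np
import pytest

from glassdev.stimgen import build_palindromic_schedule, glass_condition_labels
from glassdev.synthbold import (
    SessionConfig,
    default_ground_truth,
    simulate_session,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_schedule():
    return build_palindromic_schedule(
        glass_condition_labels(), block_duration=42.0, blank_duration=30.0, n_cycles=5
    )


@pytest.fixture(scope="session")
def adult_session(small_schedule):
    """High-signal session: every contrast with nonzero truth is decodable."""
    cfg = SessionConfig(
        age=47.0,
        n_voxels={v: 80 for v in ("V1", "V4", "MT-V5")},
        noise_sd=6.0,
        schedule=small_schedule,
        seed=7,
    )
    return simulate_session(cfg, default_ground_truth())


@pytest.fixture(scope="session")
def infant_session(small_schedule):
    """Low-signal session near the bottom of every developmental curve."""
    cfg = SessionConfig(
        age=2.0,
        n_voxels={v: 80 for v in ("V1", "V4", "MT-V5")},
        noise_sd=6.0,
        schedule=small_schedule,
        seed=8,
    )
    return simulate_session(cfg, default_ground_truth())
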