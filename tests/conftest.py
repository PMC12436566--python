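import numpy as np
import pytest
from hypothesis import settings

from sicdscreen import holter_io, synthetic_data

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def clean_recording():
    """100 s, 3 channels, constant T:R target 0.4, no noise."""
    cfg = synthetic_data.default_config(
        duration_s=100.0, seed=101, noise=synthetic_data.ZERO_NOISE
    )
    for ch in cfg.channels.values():
        ch.trajectory = synthetic_data.TRTrajectory(
            per_segment_target=np.full(10, 0.4)
        )
    return synthetic_data.generate_recording(cfg)


@pytest.fixture(scope="session")
def noisy_recording():
    """200 s, 3 channels, drifting T:R with all three noise sources."""
    cfg = synthetic_data.default_config(duration_s=200.0, seed=202)
    return synthetic_data.generate_recording(cfg)


@pytest.fixture(scope="session")
def clean_segments(clean_recording):
    recording, _ = clean_recording
    return holter_io.segment_recording(recording)


@pytest.fixture
def beat_segment():
    """Single-channel 10-s clean segment with known T:R = 0.33."""
    cfg = synthetic_data.default_config(
        duration_s=10.0, seed=7, noise=synthetic_data.ZERO_NOISE
    )
    cfg.channels["primary"].trajectory = synthetic_data.TRTrajectory(
        per_segment_target=np.array([0.33])
    )
    recording, truth = synthetic_data.generate_recording(cfg)
    seg = holter_io.segment_recording(recording)["primary"][0]
    return seg, truth["primary"][0]
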