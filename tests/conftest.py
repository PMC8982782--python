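import numpy as np
import pytest

from faceattn import SyntheticConfig, generate_cohort
from faceattn.synthetic import cohort_feature_matrix


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_participants_per_group=2, frames_per_participant=600, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    return cohort_feature_matrix(small_cohort)


def random_session(rng, n_frames=10, invalid=(), participant_id="P1", frame_rate_hz=16.0):
    """A session with uniform random coordinates; selected frames invalid."""
    from faceattn import FrameLandmarks, SessionRecording

    frames = []
    dt = 1000.0 / frame_rate_hz
    for f in range(n_frames):
        coords = rng.uniform(0, 300, size=(34, 2))
        valid = f not in invalid
        if not valid:
            coords = np.full((34, 2), np.nan)
        frames.append(
            FrameLandmarks(frame_index=f, timestamp_ms=f * dt, coords=coords, valid=valid)
        )
    return SessionRecording(
        participant_id=participant_id, frames=frames, frame_rate_hz=frame_rate_hz
    )
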