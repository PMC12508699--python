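import numpy as np
import pytest

from sptkin.simulate import SimConfig, simulate_ground_truth
from sptkin.trackio import RunConfig, Track


@pytest.fixture
def run_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def free_tracks():
    """Purely free Brownian tracks (no binding, bleaching, or boundary effects)."""
    sim = SimConfig(
        n_particles=200,
        n_frames=2000,
        field_size=(200.0, 200.0),
        lambda_on=0.0,
        lambda_nonspecific=0.0,
        bleach_rate=0.0,
        loc_sigma=0.030,
        seed=11,
    )
    tracks, truth = simulate_ground_truth(sim)
    return sim, tracks, truth


def make_track(frames, x, y, track_id="t") -> Track:
    return Track(track_id, np.asarray(frames), np.asarray(x, float), np.asarray(y, float))
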