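import numpy as np
import pytest

from cellmig import synthetic_data as sd
from cellmig.track_io import Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_trajectory(rng, n_points=None, track_id="t", gaps=False):
    """An arbitrary (not model-based) random track for property tests."""
    n = n_points or int(rng.integers(2, 40))
    if gaps:
        frames = np.sort(rng.choice(np.arange(4 * n), size=n, replace=False))
    else:
        frames = np.arange(n)
    xy = np.cumsum(rng.normal(0, 3.0, size=(n, 2)), axis=0) + rng.uniform(-50, 50, 2)
    return Trajectory(track_id, frames, xy[:, 0], xy[:, 1])


@pytest.fixture
def random_tracks(rng):
    return [random_trajectory(rng, track_id=str(i)) for i in range(100)]


TWO_COND_LAYOUT = {
    "plate": {"rows": 8, "columns": 12},
    "frame_interval_min": 1.5,
    "length_unit": "micron",
    "conditions": [
        {"name": "control", "treatment": "none", "wells": ["A1", "A2", "A3"]},
        {"name": "treated", "treatment": "inhibitor", "wells": ["B1", "B2", "B3"]},
    ],
}


@pytest.fixture(scope="session")
def demo_experiment():
    """Small two-condition plate with motile cells plus artifacts."""
    pops = {
        "control": [
            sd.PopulationSpec(name="motile", n_tracks=25, n_frames=31,
                              mean_step_length=2.0, step_length_sd=0.5,
                              turn_sd_deg=30.0),
            sd.PopulationSpec(name="debris", kind="stationary_artifact",
                              n_tracks=5, n_frames=31),
        ],
        "treated": [
            sd.PopulationSpec(name="motile", n_tracks=25, n_frames=31,
                              mean_step_length=2.0, step_length_sd=0.5,
                              turn_sd_deg=30.0),
            sd.PopulationSpec(name="debris", kind="stationary_artifact",
                              n_tracks=5, n_frames=31),
        ],
    }
    exp, truth = sd.simulate_experiment(
        TWO_COND_LAYOUT, pops, effects={"treated": 0.5}, seed=42)
    return exp, truth
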