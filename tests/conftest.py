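import numpy as np
import pytest

from walkscape.gps import GpsPointStream, LocalFrame, WalkingTrip
from walkscape.synthetic import GroundTruthConfig, generate_dataset, generate_scene


@pytest.fixture(scope="session")
def small_config():
    return GroundTruthConfig(n_participants=8, trips_per_participant=5, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """8 participants x 5 trips, all four archetypes, full trip table."""
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_scene(small_config):
    return generate_scene(small_config)


@pytest.fixture(scope="session")
def medium_dataset():
    """30 participants x 8 trips: enough per-archetype mass for k-selection."""
    return generate_dataset(
        GroundTruthConfig(n_participants=30, trips_per_participant=8, seed=21)
    )


@pytest.fixture()
def straight_trip():
    """Constant 1.2 m/s eastward walk of 500 s near the equator frame."""
    frame = LocalFrame(38.72, -9.14)
    t = np.arange(0.0, 500.0)
    x = 1.2 * t
    y = np.zeros_like(t)
    lat, lon = frame.to_latlon(x, y)
    return WalkingTrip("T1", "P1", t + 1.7e9, lat, lon, frame=frame)


def make_stream(xy, t=None, trip_id="S1", participant_id="P1",
                frame=LocalFrame(38.72, -9.14)):
    xy = np.asarray(xy, dtype=float)
    if t is None:
        t = np.arange(len(xy), dtype=float)
    lat, lon = frame.to_latlon(xy[:, 0], xy[:, 1])
    return GpsPointStream(trip_id, participant_id, np.asarray(t, float), lat, lon)
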