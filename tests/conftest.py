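import numpy as np
import pandas as pd
import pytest

from dualforage.geo import LocalProjection
from dualforage.simulate import SimConfig, simulate_landscape, simulate_tracks
from dualforage.trajectory import Trip

COLONY = (7.76, 53.78)
T0 = pd.Timestamp("2010-05-17T00:00:00", tz="UTC")


@pytest.fixture(scope="session")
def proj():
    return LocalProjection(*COLONY)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=11, n_individuals=3, n_trips_per_individual=4)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate_tracks(small_cfg)


@pytest.fixture(scope="session")
def landscape(small_cfg):
    return simulate_landscape(small_cfg)


@pytest.fixture(scope="session")
def mask(landscape):
    return landscape[0]


@pytest.fixture(scope="session")
def grid(landscape):
    return landscape[1]


def make_trip(proj, xy_km, t_hours, speeds=None, individual_id="bird1",
              complete=True):
    """Trip from planar km coordinates around the colony."""
    xy = np.asarray(xy_km, dtype=float)
    lon, lat = proj.inverse(xy[:, 0], xy[:, 1])
    t = T0 + pd.to_timedelta(np.asarray(t_hours, dtype=float), unit="h")
    if speeds is None:
        speeds = np.full(len(xy), 30.0)
    fixes = pd.DataFrame({"timestamp_utc": t, "lon": lon, "lat": lat,
                          "speed_kmh": np.asarray(speeds, dtype=float)})
    return Trip(individual_id=individual_id, fixes=fixes,
                start=fixes["timestamp_utc"].iloc[0],
                end=fixes["timestamp_utc"].iloc[-1], complete=complete)


def straight_out_back(proj, range_km=30.0, speed_kmh=40.0, step_km=2.0):
    """Radially monotone out-and-back trip due north at constant speed."""
    ys = np.concatenate([np.arange(0.0, range_km + 1e-9, step_km),
                         np.arange(range_km - step_km, -1e-9, -step_km)])
    xy = np.column_stack([np.zeros_like(ys), ys])
    t = np.arange(len(ys)) * step_km / speed_kmh
    return make_trip(proj, xy, t, speeds=np.full(len(ys), speed_kmh))
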