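import numpy as np
import pandas as pd
import pytest

from fledgelink.simulate import SimConfig, simulate_family_tracks


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Compact world: few families, early departures, short season."""
    return SimConfig(seed=101, n_families=3, departure_age_range=(60, 75),
                     hatch_window_days=10)


@pytest.fixture(scope="session")
def small_family_data(small_config):
    tracks, truths = simulate_family_tracks(small_config)
    return {t.bird_id: t for t in tracks}, {t.bird_id: t for t in truths}


def make_track(bird_id, times, lats, lons, speeds=None, **kwargs):
    """Hand-built track from explicit fix lists."""
    from fledgelink.traj import Track

    df = pd.DataFrame({
        "timestamp": pd.to_datetime(times, utc=True),
        "lat": np.asarray(lats, dtype=float),
        "lon": np.asarray(lons, dtype=float),
    })
    if speeds is not None:
        df["gps_speed_kmh"] = speeds
    return Track(bird_id, df, **kwargs)
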