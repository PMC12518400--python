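"""Trajectory segmentation: great-circle distances, flight bouts and
autumn-migration departure (day and moment).

A flight is a maximal bout of consecutive GPS intervals whose average
(position-derived) speed is at least 5 km/h.  The departure day is the
first calendar day with > 100 km southward travel between the day's first
and last fix, ending > 50 km south of the colony; the departure moment is
the fix preceding the first migratory flight (a bout with >= 30 km net
displacement starting on the departure day or the preceding day).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Literal

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088  # WGS-84 mean sphere

FLIGHT_SPEED_KMH = 5.0  # inclusive bout threshold
DEPARTURE_DAY_KM = 100.0  # strict: "more than 100 km"
DEPARTURE_SOUTH_KM = 50.0  # strict: "more than 50 km south of the colony"
MIGRATORY_FLIGHT_NET_KM = 30.0  # inclusive: "at least 30 km"
DEFAULT_GAP_CAP_MIN = 30.0  # intervals longer than this break bouts


def geodesic_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km on the WGS-84 mean sphere (haversine).

    Accepts scalars or numpy arrays (broadcasting).  Symmetric; zero iff
    the points coincide.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    if np.any(np.abs(lat1) > 90) or np.any(np.abs(lat2) > 90) or \
       np.any(np.abs(lon1) > 180) or np.any(np.abs(lon2) > 180):
        raise ValueError("coordinates out of range: |lat| <= 90, |lon| <= 180 required")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def geodesic_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres (see :func:`geodesic_km`)."""
    return geodesic_km(lat1, lon1, lat2, lon2) * 1000.0


@dataclass
class Track:
    """One bird's ordered GPS fixes.

    ``fixes`` is a DataFrame with columns timestamp (tz-aware UTC), lat,
    lon and optionally gps_speed_kmh (the logger's instantaneous speed,
    kept for classification features; segmentation uses position-derived
    speeds).
    """

    bird_id: str
    fixes: pd.DataFrame
    colony_latlon: tuple[float, float] | None = None
    nest_latlon: tuple[float, float] | None = None
    role: str = ""  # chick | mother | father

    def __post_init__(self) -> None:
        df = self.fixes
        for col in ("timestamp", "lat", "lon"):
            if col not in df.columns:
                raise ValueError(f"track fixes require column {col!r}")
        ts = pd.to_datetime(df["timestamp"], utc=True)
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError(f"track {self.bird_id}: timestamps must be strictly increasing")
        if (df["lat"].abs() > 90).any() or (df["lon"].abs() > 180).any():
            raise ValueError(f"track {self.bird_id}: coordinates out of range")
        df = df.copy()
        df["timestamp"] = ts
        object.__setattr__(self, "fixes", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def timestamps(self) -> pd.Series:
        return self.fixes["timestamp"]


@dataclass(frozen=True)
class FlightBout:
    start_fix_index: int
    end_fix_index: int  # index of the bout's last fix; end > start
    net_displacement_km: float
    mean_speed_kmh: float

    def __post_init__(self) -> None:
        if self.end_fix_index <= self.start_fix_index:
            raise ValueError("a flight bout must span at least one interval")


@dataclass(frozen=True)
class DepartureEvent:
    bird_id: str
    departure_day: date
    departure_moment: pd.Timestamp
    first_migratory_flight: FlightBout


class DepartureInconsistencyError(RuntimeError):
    """Day-level departure rule fired but no migratory flight bout (>= 30 km
    net) starts on the departure day or the preceding day."""


def _interval_speeds(track: Track) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval average speed (km/h, displacement over elapsed time)
    and interval duration in minutes."""
    df = track.fixes
    lat, lon = df["lat"].to_numpy(), df["lon"].to_numpy()
    d_km = geodesic_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
    dt_h = np.diff(df["timestamp"].astype("int64").to_numpy()) / 3.6e12
    return d_km / dt_h, dt_h * 60.0


def detect_flight_bouts(
    track: Track,
    speed_threshold_kmh: float = FLIGHT_SPEED_KMH,
    gap_cap_min: float = DEFAULT_GAP_CAP_MIN,
) -> list[FlightBout]:
    """Maximal runs of consecutive intervals with average speed >= threshold.

    Intervals longer than ``gap_cap_min`` minutes never join a bout (they
    break runs), so sparse post-departure fixes do not produce spurious
    multi-hour "flights".
    """
    if len(track) < 2:
        raise ValueError("flight-bout detection requires at least 2 fixes")
    speeds, dur_min = _interval_speeds(track)
    fast = (speeds >= speed_threshold_kmh) & (dur_min <= gap_cap_min)
    df = track.fixes
    bouts: list[FlightBout] = []
    i = 0
    n = len(fast)
    while i < n:
        if not fast[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and fast[j + 1]:
            j += 1
        start, end = i, j + 1  # fix indices
        net = float(
            geodesic_km(
                df["lat"].iat[start], df["lon"].iat[start],
                df["lat"].iat[end], df["lon"].iat[end],
            )
        )
        elapsed_h = (
            df["timestamp"].iat[end] - df["timestamp"].iat[start]
        ).total_seconds() / 3600.0
        path_km = float(np.sum(geodesic_km(
            df["lat"].to_numpy()[start:end], df["lon"].to_numpy()[start:end],
            df["lat"].to_numpy()[start + 1:end + 1], df["lon"].to_numpy()[start + 1:end + 1],
        )))
        bouts.append(FlightBout(start, end, net, path_km / elapsed_h))
        i = j + 1
    return bouts


SouthwardMetric = Literal["geodesic", "latitudinal"]


def detect_departure_day(
    track: Track,
    colony_latlon: tuple[float, float] | None = None,
    min_travel_km: float = DEPARTURE_DAY_KM,
    min_south_of_colony_km: float = DEPARTURE_SOUTH_KM,
    southward_metric: SouthwardMetric = "geodesic",
    day_offset_hours: float = 0.0,
) -> date | None:
    """First calendar day qualifying as the autumn-migration departure day.

    Conditions, both evaluated between the day's first and last fix:
    (i) travel > ``min_travel_km`` in southward direction (last fix at lower
    latitude; distance geodesic by default, or pure latitudinal via
    ``southward_metric='latitudinal'``), and (ii) the day's last fix lies
    more than ``min_south_of_colony_km`` km south of the colony, measured
    as north-south (latitudinal) separation.  Days are UTC calendar days,
    optionally shifted by ``day_offset_hours``.
    """
    colony = colony_latlon or track.colony_latlon
    if colony is None:
        raise ValueError("colony coordinates required for departure detection")
    df = track.fixes
    ts = df["timestamp"] - pd.Timedelta(hours=day_offset_hours)
    for day, idx in df.groupby(ts.dt.date).groups.items():
        first, last = idx[0], idx[-1]
        lat0, lon0 = df["lat"].at[first], df["lon"].at[first]
        lat1, lon1 = df["lat"].at[last], df["lon"].at[last]
        if lat1 >= lat0:  # not southward
            continue
        if southward_metric == "geodesic":
            travel = float(geodesic_km(lat0, lon0, lat1, lon1))
        else:
            travel = float(geodesic_km(lat0, lon0, lat1, lon0))
        if travel <= min_travel_km:
            continue
        if lat1 >= colony[0]:
            continue
        south_of_colony = float(geodesic_km(colony[0], lon1, lat1, lon1))
        if south_of_colony > min_south_of_colony_km:
            return day
    return None


def detect_departure_moment(
    track: Track,
    departure_day: date,
    min_net_km: float = MIGRATORY_FLIGHT_NET_KM,
    speed_threshold_kmh: float = FLIGHT_SPEED_KMH,
    gap_cap_min: float = DEFAULT_GAP_CAP_MIN,
    day_offset_hours: float = 0.0,
) -> DepartureEvent:
    """Departure moment: the fix preceding the first migratory flight.

    The first migratory flight is the earliest flight bout with net
    displacement >= ``min_net_km`` starting on ``departure_day`` or the
    preceding calendar day (covering birds that leave the evening before).
    """
    bouts = detect_flight_bouts(track, speed_threshold_kmh, gap_cap_min)
    df = track.fixes
    eve = departure_day - timedelta(days=1)
    ts = df["timestamp"] - pd.Timedelta(hours=day_offset_hours)
    candidates = [
        b for b in bouts
        if b.net_displacement_km >= min_net_km
        and ts.iat[b.start_fix_index].date() in (departure_day, eve)
    ]
    if not candidates:
        raise DepartureInconsistencyError(
            f"{track.bird_id}: departure day {departure_day} found but no flight bout "
            f"with net displacement >= {min_net_km} km starts on that day or its eve"
        )
    first = min(candidates, key=lambda b: b.start_fix_index)
    # the bout's start fix is the last fix at which the bird has not yet
    # moved: the fix preceding the migratory flight
    moment_idx = first.start_fix_index
    return DepartureEvent(
        bird_id=track.bird_id,
        departure_day=departure_day,
        departure_moment=df["timestamp"].iat[moment_idx],
        first_migratory_flight=first,
    )


def detect_departure(track: Track, colony_latlon=None, **kwargs) -> DepartureEvent | None:
    """Convenience wrapper: day rule then moment rule; None if no departure."""
    day = detect_departure_day(track, colony_latlon, day_offset_hours=kwargs.get("day_offset_hours", 0.0))
    if day is None:
        return None
    return detect_departure_moment(track, day, **kwargs)


def distance_to_nest(track: Track, at: pd.Timestamp, nest_latlon=None) -> float:
    """Distance (km) from the fix nearest in time to ``at`` to the nest."""
    nest = nest_latlon or track.nest_latlon
    if nest is None:
        raise ValueError("nest coordinates required")
    if len(track) == 0:
        raise ValueError("empty track")
    at = pd.Timestamp(at)
    if at.tzinfo is None:
        at = at.tz_localize("UTC")
    dt = (track.fixes["timestamp"] - at).abs()
    i = int(dt.to_numpy().argmin())
    return float(geodesic_km(track.fixes["lat"].iat[i], track.fixes["lon"].iat[i], nest[0], nest[1]))
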