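"""Synthetic family tracking data.

Generates parent-chick GPS tracks, tri-axial acceleration bursts and
colour-ring feeding observations with the statistical structure the
downstream analysis assumes: 10-min GPS cadence near the colony with
random dropout, coarse 1-6 h "GSM" fixes after migration departure,
logistic age/year-dependent contact episodes with per-chick random
heterogeneity, behaviour-specific acceleration signatures including the
chick-only class 'beg', and Poisson feeding counts declining with age.

The movement model is deliberately minimal: a biased random walk anchored
to the colony before departure, and straight-line 40-60 km/h southward
flight on migration — the simplest construction that exercises every
detector threshold (5 km/h flight bouts, 30 km migratory flights,
100 km/50 km departure days, 10/50 m contact, 25 km post-departure
proximity).

Positional error is applied to the underlying path; metre-scale contact
offsets are then placed in the measured frame (parent fix = recorded chick
position + offset), so an injected contact episode is a statement about
recorded proximity and is recoverable at the 10 m threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, timedelta, timezone
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .traj import Track, EARTH_RADIUS_KM

M_PER_DEG_LAT = EARTH_RADIUS_KM * 1000.0 * math.pi / 180.0

BEHAVIOUR_CLASSES = (
    "search", "handle", "ingest", "sit", "stand",
    "fly-active", "fly-passive", "walk", "beg",
)

#: Acceleration signature per behaviour: static posture per axis (g),
#: periodic component (frequency Hz, per-axis amplitude g), noise SD (g)
#: and the GPS-speed range (km/h).  The literature gives no waveforms for
#: these behaviours; this table is the package's frozen stated world.
#: 'beg' is the chick's head-pumping display: a low-frequency,
#: large-amplitude heave/surge oscillation.  'fly-active' is
#: high-frequency flapping; 'sit'/'stand' are near-static and separated by
#: posture; 'fly-passive' (gliding) is near-static at flight speed.
CLASS_SIGNATURES: dict[str, dict] = {
    "search":      {"posture": (0.30, 0.00, 0.90), "freq": 2.6, "amp": (0.12, 0.28, 0.10), "noise": 0.20, "speed": (0.0, 2.0)},
    "handle":      {"posture": (0.25, 0.00, 0.90), "freq": 3.2, "amp": (0.18, 0.15, 0.18), "noise": 0.25, "speed": (0.0, 1.5)},
    "ingest":      {"posture": (0.20, 0.00, 0.95), "freq": 4.0, "amp": (0.10, 0.05, 0.32), "noise": 0.22, "speed": (0.0, 1.5)},
    "sit":         {"posture": (0.05, 0.00, 0.60), "freq": 0.0, "amp": (0.00, 0.00, 0.00), "noise": 0.10, "speed": (0.0, 0.5)},
    "stand":       {"posture": (0.05, 0.00, 1.00), "freq": 0.0, "amp": (0.00, 0.00, 0.00), "noise": 0.10, "speed": (0.0, 1.0)},
    "fly-active":  {"posture": (0.30, 0.00, 0.50), "freq": 5.5, "amp": (0.30, 0.10, 0.90), "noise": 0.25, "speed": (20.0, 60.0)},
    "fly-passive": {"posture": (0.10, 0.00, 0.80), "freq": 0.0, "amp": (0.00, 0.00, 0.00), "noise": 0.12, "speed": (20.0, 60.0)},
    "walk":        {"posture": (0.15, 0.00, 0.95), "freq": 1.8, "amp": (0.20, 0.08, 0.35), "noise": 0.18, "speed": (1.0, 4.0)},
    "beg":         {"posture": (0.25, 0.00, 0.85), "freq": 1.4, "amp": (0.50, 0.10, 0.80), "noise": 0.20, "speed": (0.0, 2.0)},
}

#: Pre-departure behaviour frequencies outside contact moments (no 'beg':
#: begging happens at a parent).
DEFAULT_BEHAVIOUR_FREQS: dict[str, float] = {
    "search": 0.20, "handle": 0.05, "ingest": 0.05, "sit": 0.25,
    "stand": 0.22, "fly-active": 0.06, "fly-passive": 0.04, "walk": 0.13,
}


@dataclass
class SimConfig:
    """Stated world of the synthetic colony.

    Contact probability for a chick of age ``a`` (days) in year ``y``:
    ``logit p = baseline_contact_odds + contact_decay_rate*(a-35)
    + year_effects[y] + b0_chick + b1_chick*(a-35)`` with correlated
    per-chick random effects (SDs ``contact_sd_intercept`` /
    ``contact_sd_slope``, correlation ``contact_re_corr``).
    """

    seed: int = 0
    n_families: int = 15
    colony_latlon: tuple[float, float] = (53.4833, 6.25)
    gps_interval_min: float = 10.0
    years: tuple[int, ...] = (2016, 2017, 2018)
    hatch_start_monthday: str = "04-25"
    hatch_window_days: int = 25
    study_end_monthday: str = "11-30"
    # contact process (per-day log-odds scale)
    baseline_contact_odds: float = -2.3   # logit of contact at age 35 d
    contact_decay_rate: float = -0.03     # log-odds per day of age
    year_effects: dict = field(default_factory=lambda: {2016: 0.0, 2017: -1.5, 2018: 0.5})
    contact_sd_intercept: float = 1.0
    contact_sd_slope: float = 0.02
    contact_re_corr: float = -0.2
    beg_given_contact: float = 0.2
    contact_max_m: float = 5.0
    noncontact_min_m: float = 60.0
    noncontact_max_m: float = 3000.0
    # departure
    departure_age_range: tuple[int, int] = (108, 139)
    frac_no_departure: float = 0.13
    evening_departure_frac: float = 0.2
    joint_departure: bool = True
    frac_two_parents: float = 0.2
    # sampling artefacts
    dropout_rate: float = 0.05
    gps_error_m: float = 3.0
    timestamp_jitter_s: float = 30.0
    gsm_interval_h: tuple[float, float] = (1.0, 6.0)
    post_departure_days: int = 10
    # acceleration
    acc_rate_hz: float = 20.0
    burst_len_s: float = 1.6
    acc_noise: float = 1.0
    acc_missing_rate: float = 0.05
    behaviour_freqs: dict = field(default_factory=lambda: dict(DEFAULT_BEHAVIOUR_FREQS))
    # feeding observations
    n_ringed_chicks: int = 127
    feeding_log_intercept: float = 0.6    # log expected count in a 10-d class at age 0
    feeding_log_slope: float = -0.035     # per day of age
    feeding_dist_intercept_km: float = -2.0
    feeding_dist_slope_km_per_day: float = 0.12
    feeding_dist_sd_km: float = 5.0
    frac_parent_unringed: float = 0.18
    sex_evidence_error_rate: float = 0.10

    def __post_init__(self) -> None:
        if self.gps_interval_min <= 0:
            raise ValueError("gps_interval_min must be positive")
        npts = self.burst_len_s * self.acc_rate_hz
        if abs(npts - round(npts)) > 1e-9 or round(npts) < 8:
            raise ValueError("burst_len_s * acc_rate_hz must be an integer >= 8")
        lo, hi = self.departure_age_range
        if not (35 < lo <= hi < 200):
            raise ValueError("departure_age_range must lie within (35, 200)")

    @property
    def burst_npts(self) -> int:
        return int(round(self.burst_len_s * self.acc_rate_hz))


@dataclass
class TrueItinerary:
    """Ground truth for one bird (recovery tests join against this)."""

    bird_id: str
    family_id: str
    role: str  # chick | mother | father
    sex: str  # female | male
    year: int
    hatch_date: date  # the family chick's hatch date
    chick_id: str
    partner_ids: tuple[str, ...]
    departure_day: date | None
    departure_moment: pd.Timestamp | None
    # chick only; both keyed by the chick fix timestamp (incl. dropped fixes)
    behaviours: pd.DataFrame | None = None     # timestamp, behaviour
    contacts: pd.DataFrame | None = None       # timestamp, partner_id, in_contact, true_distance_m
    daily_state: pd.DataFrame | None = None    # date, state


# ----------------------------------------------------------------------
# geometry helpers

def _metres_to_deg(north_m, east_m, lat0: float):
    dlat = np.asarray(north_m) / M_PER_DEG_LAT
    dlon = np.asarray(east_m) / (M_PER_DEG_LAT * math.cos(math.radians(lat0)))
    return dlat, dlon


def _offset_latlon(lat, lon, north_m, east_m):
    dlat, dlon = _metres_to_deg(north_m, east_m, float(np.mean(lat)))
    return lat + dlat, lon + dlon


def _ar1(n: int, phi: float, step_sd: float, rng) -> np.ndarray:
    """Mean-zero AR(1) path (metres)."""
    eps = rng.normal(0.0, step_sd, n)
    out = np.empty(n)
    acc = 0.0
    for i in range(n):
        acc = phi * acc + eps[i]
        out[i] = acc
    return out


# ----------------------------------------------------------------------
# track construction

def _season_dates(cfg: SimConfig, year: int) -> tuple[date, date]:
    m, d = (int(x) for x in cfg.hatch_start_monthday.split("-"))
    m2, d2 = (int(x) for x in cfg.study_end_monthday.split("-"))
    return date(year, m, d), date(year, m2, d2)


def _migration_path(start_lat, start_lon, dep_moment: pd.Timestamp,
                    end_ts: pd.Timestamp, cfg: SimConfig, rng,
                    route_seed_bearing: float | None = None):
    """Southbound migration fixes: 10-min cadence during the first
    migratory flight (antenna still in range), then 1-6 h GSM fixes with
    daily travel blocks."""
    times: list[pd.Timestamp] = []
    lats: list[float] = []
    lons: list[float] = []
    speed_kmh = rng.uniform(45.0, 55.0)
    bearing = route_seed_bearing if route_seed_bearing is not None else rng.normal(180.0, 8.0)
    flight_h = rng.uniform(5.0, 8.0)
    lat, lon = start_lat, start_lon
    t = dep_moment
    step_h = cfg.gps_interval_min / 60.0
    n_steps = int(flight_h / step_h)
    for _ in range(n_steps):
        t = t + pd.Timedelta(minutes=cfg.gps_interval_min)
        d_km = speed_kmh * step_h
        north = -d_km * 1000.0 * math.cos(math.radians(bearing - 180.0))
        east = d_km * 1000.0 * math.sin(math.radians(bearing))
        dlat, dlon = _metres_to_deg(north, east, lat)
        lat, lon = lat + float(dlat), lon + float(dlon)
        times.append(t)
        lats.append(lat)
        lons.append(lon)
    # subsequent GSM phase: sparse fixes, some travel days
    while t < end_ts:
        gap_h = rng.uniform(*cfg.gsm_interval_h)
        t = t + pd.Timedelta(hours=gap_h)
        if t >= end_ts:
            break
        if rng.random() < 0.35:  # travelling during this gap
            d_km = rng.uniform(20.0, 60.0) * gap_h / 6.0 * rng.uniform(2.0, 5.0)
            d_km = min(d_km, 55.0 * gap_h)
            north = -d_km * 1000.0 * math.cos(math.radians(bearing - 180.0))
            east = d_km * 1000.0 * math.sin(math.radians(rng.normal(bearing, 10.0)))
            dlat, dlon = _metres_to_deg(north, east, lat)
            lat, lon = lat + float(dlat), lon + float(dlon)
        times.append(t)
        lats.append(lat)
        lons.append(lon)
    speeds = np.full(len(times), 0.0)
    if n_steps:
        speeds[:n_steps] = speed_kmh
    # millisecond precision: fine for 10-min data, survives CSV round-trips
    idx = pd.DatetimeIndex(times).round("ms") if times else pd.DatetimeIndex([], tz="UTC")
    return (idx, np.asarray(lats), np.asarray(lons), speeds)


def _draw_departure(dep_day: date, cfg: SimConfig, rng) -> pd.Timestamp:
    """Departure *moment* consistent with ``dep_day`` being the day-rule
    day: usually a morning/afternoon start that day, sometimes late in the
    evening before (the flight then crosses midnight with < 100 km
    travelled on the eve)."""
    if rng.random() < cfg.evening_departure_frac:
        h = rng.uniform(22.5, 23.8)
        d = dep_day - timedelta(days=1)
    else:
        h = rng.uniform(8.0, 16.0)
        d = dep_day
    base = pd.Timestamp(datetime(d.year, d.month, d.day, tzinfo=timezone.utc))
    return (base + pd.Timedelta(hours=h)).round("ms")


def _grid(start: pd.Timestamp, end: pd.Timestamp, interval_min: float) -> pd.DatetimeIndex:
    return pd.date_range(start, end, freq=pd.Timedelta(minutes=interval_min), inclusive="left")


def _simulate_family(ix: int, cfg: SimConfig, rng):
    """One family: chick + 1-2 tagged parents, their tracks and truths."""
    year = cfg.years[ix % len(cfg.years)]
    family_id = f"F{ix:02d}"
    chick_id = f"{family_id}-chick"
    hatch_start, study_end = _season_dates(cfg, year)
    hatch = hatch_start + timedelta(days=int(rng.integers(0, cfg.hatch_window_days + 1)))
    nest_north, nest_east = rng.uniform(-100, 100, 2)
    nlat, nlon = _offset_latlon(np.array(cfg.colony_latlon[0]), np.array(cfg.colony_latlon[1]),
                                nest_north, nest_east)
    nest = (float(nlat), float(nlon))

    track_start = pd.Timestamp(datetime(hatch.year, hatch.month, hatch.day, tzinfo=timezone.utc)) \
        + pd.Timedelta(days=35)
    study_end_ts = pd.Timestamp(datetime(study_end.year, study_end.month, study_end.day,
                                         23, 59, tzinfo=timezone.utc))

    migrates = rng.random() >= cfg.frac_no_departure
    if migrates:
        dep_age = int(rng.integers(cfg.departure_age_range[0], cfg.departure_age_range[1] + 1))
        dep_day = hatch + timedelta(days=dep_age)
        dep_moment = _draw_departure(dep_day, cfg, rng)
        chick_end = min(study_end_ts,
                        pd.Timestamp(dep_day, tz="UTC") + pd.Timedelta(days=cfg.post_departure_days))
    else:
        dep_day, dep_moment = None, None
        chick_end = study_end_ts

    pre_end = dep_moment if dep_moment is not None else chick_end
    slots = _grid(track_start, pre_end, cfg.gps_interval_min)
    n = len(slots)
    ages = ((slots.tz_convert("UTC").normalize() - pd.Timestamp(hatch, tz="UTC"))
            / pd.Timedelta(days=1)).astype(int).to_numpy()

    # chick pre-departure positions: AR(1) wander around a daily site
    day_codes = pd.factorize(slots.date)[0]
    n_days = day_codes.max() + 1
    site_n = np.cumsum(rng.normal(0, 800, n_days))  # slow day-to-day drift (m)
    site_e = np.cumsum(rng.normal(0, 800, n_days))
    site_n = np.clip(site_n, -6000, 6000)
    site_e = np.clip(site_e, -6000, 6000)
    wander_n = _ar1(n, 0.95, 50.0, rng) + site_n[day_codes]
    wander_e = _ar1(n, 0.95, 50.0, rng) + site_e[day_codes]
    err = rng.normal(0.0, cfg.gps_error_m, (n, 2))
    chick_lat, chick_lon = _offset_latlon(
        np.full(n, nest[0]), np.full(n, nest[1]),
        wander_n + err[:, 0], wander_e + err[:, 1])

    # per-chick random effects on the contact log-odds
    cov = np.array([
        [cfg.contact_sd_intercept ** 2,
         cfg.contact_re_corr * cfg.contact_sd_intercept * cfg.contact_sd_slope],
        [cfg.contact_re_corr * cfg.contact_sd_intercept * cfg.contact_sd_slope,
         cfg.contact_sd_slope ** 2]])
    b0, b1 = rng.multivariate_normal([0.0, 0.0], cov)
    logit_p = (cfg.baseline_contact_odds + b0
               + (cfg.contact_decay_rate + b1) * (ages - 35)
               + cfg.year_effects.get(year, 0.0))
    p_contact = expit(logit_p)

    n_parents = 2 if rng.random() < cfg.frac_two_parents else 1
    roles = ["mother", "father"] if n_parents == 2 else [rng.choice(["mother", "father"])]

    # chick fix jitter and dropout
    chick_jit = rng.uniform(-cfg.timestamp_jitter_s, cfg.timestamp_jitter_s, n)
    chick_ts = (slots + pd.to_timedelta(chick_jit, unit="s")).round("ms")
    chick_keep = rng.random(n) >= cfg.dropout_rate

    parents = []
    any_contact = np.zeros(n, dtype=bool)
    contact_rows = []
    for pi, role in enumerate(roles):
        parent_id = f"{family_id}-{role}"
        if migrates and cfg.joint_departure and ix == 0:
            p_dep_moment = dep_moment + pd.Timedelta(minutes=4)
            p_dep_day = dep_day
        else:
            p_dep_age = int(rng.integers(80, 136))
            p_dep_day_ = hatch + timedelta(days=p_dep_age)
            if pd.Timestamp(p_dep_day_, tz="UTC") >= study_end_ts - pd.Timedelta(days=12):
                p_dep_day_ = study_end - timedelta(days=12)
            p_dep_day = p_dep_day_
            p_dep_moment = _draw_departure(p_dep_day, cfg, rng)
        pre_mask = slots < p_dep_moment  # parent anchored to chick before its departure
        contact = (rng.random(n) < p_contact) & pre_mask
        any_contact |= contact
        dist = np.where(
            contact,
            rng.uniform(0.5, cfg.contact_max_m - 0.5, n),
            rng.uniform(cfg.noncontact_min_m, cfg.noncontact_max_m, n))
        bearing = rng.uniform(0, 2 * math.pi, n)
        plat, plon = _offset_latlon(chick_lat, chick_lon,
                                    dist * np.cos(bearing), dist * np.sin(bearing))
        perr = np.where(contact[:, None], 0.0, rng.normal(0.0, cfg.gps_error_m, (n, 2)))
        plat, plon = _offset_latlon(plat, plon, perr[:, 0], perr[:, 1])
        pjit = rng.uniform(-cfg.timestamp_jitter_s, cfg.timestamp_jitter_s, n)
        pts = (slots + pd.to_timedelta(pjit, unit="s")).round("ms")
        pkeep = (rng.random(n) >= cfg.dropout_rate) & pre_mask
        pspeed = np.abs(rng.normal(0.8, 0.6, n))

        p_end = min(study_end_ts, p_dep_moment + pd.Timedelta(days=cfg.post_departure_days))
        mt, mlat, mlon, mspeed = _migration_path(
            float(plat[pre_mask][-1]) if pre_mask.any() else nest[0],
            float(plon[pre_mask][-1]) if pre_mask.any() else nest[1],
            p_dep_moment, p_end, cfg, rng,
            route_seed_bearing=180.0 if (migrates and cfg.joint_departure and ix == 0) else None)
        fixes = pd.DataFrame({
            "timestamp": pts[pkeep].append(pd.DatetimeIndex(mt)),
            "lat": np.concatenate([plat[pkeep], mlat]),
            "lon": np.concatenate([plon[pkeep], mlon]),
            "gps_speed_kmh": np.concatenate([pspeed[pkeep], mspeed]),
        })
        fixes = fixes[~fixes["timestamp"].duplicated()].sort_values("timestamp")
        ptrack = Track(parent_id, fixes, colony_latlon=cfg.colony_latlon,
                       nest_latlon=nest, role=role)
        ptruth = TrueItinerary(
            bird_id=parent_id, family_id=family_id, role=role,
            sex="female" if role == "mother" else "male", year=year,
            hatch_date=hatch, chick_id=chick_id, partner_ids=(chick_id,),
            departure_day=p_dep_moment.date() if p_dep_moment.hour < 22 else
            (p_dep_moment + pd.Timedelta(days=1)).date(),
            departure_moment=p_dep_moment)
        parents.append((ptrack, ptruth))
        contact_rows.append(pd.DataFrame({
            "timestamp": chick_ts, "partner_id": parent_id,
            "in_contact": contact, "true_distance_m": dist,
            "chick_age": ages,
        }))

    # chick behaviours: 'beg' only at a parent (during contact)
    freq_names = list(cfg.behaviour_freqs)
    freq_p = np.array([cfg.behaviour_freqs[k] for k in freq_names], dtype=float)
    freq_p = freq_p / freq_p.sum()
    beh = np.asarray(rng.choice(freq_names, size=n, p=freq_p), dtype=object)
    begging = any_contact & (rng.random(n) < cfg.beg_given_contact)
    beh[begging] = "beg"

    chick_speed = np.empty(n)
    for cls in set(beh):
        m = beh == cls
        lo, hi = CLASS_SIGNATURES[cls]["speed"]
        chick_speed[m] = rng.uniform(lo, hi, int(m.sum()))

    if migrates:
        mt, mlat, mlon, mspeed = _migration_path(
            float(chick_lat[-1]), float(chick_lon[-1]), dep_moment, chick_end, cfg, rng,
            route_seed_bearing=180.0 if (cfg.joint_departure and ix == 0) else None)
        mig_beh = pd.DataFrame({
            "timestamp": mt,
            "behaviour": np.asarray(rng.choice(["fly-active", "fly-passive"], size=len(mt),
                                               p=[0.7, 0.3]), dtype=object)})
    else:
        mt, mlat, mlon, mspeed = (pd.DatetimeIndex([], tz="UTC"),
                                  np.array([]), np.array([]), np.array([]))
        mig_beh = pd.DataFrame(columns=["timestamp", "behaviour"])

    fixes = pd.DataFrame({
        "timestamp": chick_ts[chick_keep].append(pd.DatetimeIndex(mt)),
        "lat": np.concatenate([chick_lat[chick_keep], mlat]),
        "lon": np.concatenate([chick_lon[chick_keep], mlon]),
        "gps_speed_kmh": np.concatenate([chick_speed[chick_keep], mspeed]),
    })
    fixes = fixes[~fixes["timestamp"].duplicated()].sort_values("timestamp")
    chick_track = Track(chick_id, fixes, colony_latlon=cfg.colony_latlon,
                        nest_latlon=nest, role="chick")

    behaviours = pd.DataFrame({"timestamp": chick_ts, "behaviour": beh})
    if len(mig_beh):
        behaviours = pd.concat([behaviours, mig_beh], ignore_index=True)
    contacts = pd.concat(contact_rows, ignore_index=True)
    state = pd.DataFrame({
        "date": pd.date_range(track_start.date(), chick_end.date(), freq="D").date,
    })
    state["state"] = "at-colony"
    if dep_day is not None:
        state.loc[state["date"] >= dep_day, "state"] = "migrating"
    chick_truth = TrueItinerary(
        bird_id=chick_id, family_id=family_id, role="chick",
        sex=str(rng.choice(["female", "male"])), year=year,
        hatch_date=hatch, chick_id=chick_id,
        partner_ids=tuple(p[0].bird_id for p in parents),
        departure_day=dep_day, departure_moment=dep_moment,
        behaviours=behaviours, contacts=contacts, daily_state=state)

    return [(chick_track, chick_truth)] + parents


def simulate_family_tracks(cfg: SimConfig) -> tuple[list[Track], list[TrueItinerary]]:
    """Simulate all families' GPS tracks and the ground truth behind them."""
    if cfg.n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    tracks: list[Track] = []
    truths: list[TrueItinerary] = []
    for ix in range(cfg.n_families):
        for track, truth in _simulate_family(ix, cfg, rng):
            tracks.append(track)
            truths.append(truth)
    return tracks, truths


# ----------------------------------------------------------------------
# acceleration bursts

def _burst(cls: str, cfg: SimConfig, rng, npts: int | None = None) -> np.ndarray:
    sig = CLASS_SIGNATURES[cls]
    npts = cfg.burst_npts if npts is None else npts
    t = np.arange(npts) / cfg.acc_rate_hz
    out = np.empty((npts, 3))
    # all within-class variability scales with the noise knob, so
    # acc_noise=0 is a degenerate world with identical per-class waveforms
    cap = min(cfg.acc_noise, 1.0)
    freq = sig["freq"] * rng.uniform(1 - 0.1 * cap, 1 + 0.1 * cap) if sig["freq"] else 0.0
    phase = rng.uniform(0, 2 * math.pi) * cap
    amp_jit = rng.lognormal(0.0, 0.15 * cap)
    for a in range(3):
        base = sig["posture"][a] + rng.normal(0.0, 0.05 * cap)
        wave = sig["amp"][a] * amp_jit * np.sin(2 * math.pi * freq * t + phase) if freq else 0.0
        noise = rng.normal(0.0, sig["noise"] * cfg.acc_noise, npts)
        out[:, a] = base + wave + noise
    return out


def simulate_acc_bursts(truth: TrueItinerary, cfg: SimConfig) -> list:
    """Acceleration bursts for every behaviour-labelled fix of a chick.

    Each burst is ``burst_len_s * acc_rate_hz`` tri-axial readings drawn
    from the class signature table; about ``acc_missing_rate`` of bursts
    are truncated or missing entirely, emulating interrupted downloads.
    """
    from .acc import AccSample

    if truth.behaviours is None:
        raise ValueError("truth has no behaviour labels (not a chick itinerary?)")
    import zlib

    rng = np.random.default_rng((cfg.seed, zlib.crc32(truth.bird_id.encode())))
    samples: list[AccSample] = []
    for row in truth.behaviours.itertuples():
        u = rng.random()
        if u < cfg.acc_missing_rate / 2.0:
            continue  # missing entirely
        npts = cfg.burst_npts
        if u < cfg.acc_missing_rate:
            npts = int(rng.integers(max(4, cfg.burst_npts // 4), cfg.burst_npts))
        cls = row.behaviour
        lo, hi = CLASS_SIGNATURES[cls]["speed"]
        samples.append(AccSample(
            bird_id=truth.bird_id,
            burst_start=pd.Timestamp(row.timestamp),
            readings=_burst(cls, cfg, rng, npts),
            gps_speed_kmh=float(rng.uniform(lo, hi)),
            behaviour=cls,
        ))
    return samples


def simulate_labelled_bursts(cfg: SimConfig, n_per_class: int, seed: int | None = None,
                             classes: Sequence[str] = BEHAVIOUR_CLASSES) -> list:
    """Balanced annotated training material: ``n_per_class`` complete
    bursts per behaviour class (a synthetic stand-in for video-annotated
    data).  Missingness is not applied: annotation implies a full burst."""
    from .acc import AccSample

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    t0 = pd.Timestamp("2016-07-01", tz="UTC")
    samples: list[AccSample] = []
    k = 0
    for cls in classes:
        lo, hi = CLASS_SIGNATURES[cls]["speed"]
        for _ in range(n_per_class):
            samples.append(AccSample(
                bird_id="annotated",
                burst_start=t0 + pd.Timedelta(seconds=10 * k),
                readings=_burst(cls, cfg, rng),
                gps_speed_kmh=float(rng.uniform(lo, hi)),
                behaviour=cls,
            ))
            k += 1
    return samples


# ----------------------------------------------------------------------
# feeding observations

def simulate_feeding_observations(cfg: SimConfig, n_chicks: int | None = None) -> pd.DataFrame:
    """Colour-ring feeding-observation records.

    Per chick and 10-day age class, observation counts are Poisson with a
    log-linear age trend; feeding distance from the colony trends upward
    with age; a fraction of feeding parents is unringed; ringed parents
    carry visual sex-evidence situation codes (1-7) with a configurable
    per-record error rate.
    """
    rng = np.random.default_rng((cfg.seed, 7919))
    n_chicks = cfg.n_ringed_chicks if n_chicks is None else n_chicks
    cols = ["chick_id", "chick_sex", "age_days", "age_class", "date", "year",
            "distance_km", "parent_id", "parent_ringed", "parent_sex",
            "evidence_code", "evidence_claimed_sex"]
    if n_chicks == 0:
        return pd.DataFrame(columns=cols)
    rows = []
    for c in range(n_chicks):
        chick_id = f"C{c:04d}"
        year = int(rng.choice(cfg.years))
        hatch = date(year, 4, 25) + timedelta(days=int(rng.integers(0, 26)))
        chick_sex = rng.choice(["female", "male"])
        parent_ringed = rng.random() >= cfg.frac_parent_unringed
        parent_id = f"P{c:04d}" if parent_ringed else None
        parent_sex = rng.choice(["female", "male"])
        for mid in range(40, 140, 10):
            lam = math.exp(cfg.feeding_log_intercept + cfg.feeding_log_slope * mid)
            for _ in range(rng.poisson(lam)):
                age = float(rng.uniform(mid - 5, mid + 5))
                dist = (cfg.feeding_dist_intercept_km
                        + cfg.feeding_dist_slope_km_per_day * age
                        + rng.normal(0.0, cfg.feeding_dist_sd_km))
                dist = float(np.clip(dist, 0.2, 45.0))
                if parent_ringed:
                    code = int(rng.choice([1, 2, 3, 4, 5, 6, 7]))
                    wrong = rng.random() < cfg.sex_evidence_error_rate
                    claimed = parent_sex if not wrong else \
                        ("male" if parent_sex == "female" else "female")
                else:
                    code, claimed = None, None
                rows.append({
                    "chick_id": chick_id, "chick_sex": chick_sex,
                    "age_days": age, "age_class": mid,
                    "date": hatch + timedelta(days=int(age)), "year": year,
                    "distance_km": dist,
                    "parent_id": parent_id, "parent_ringed": parent_ringed,
                    "parent_sex": parent_sex,
                    "evidence_code": code, "evidence_claimed_sex": claimed,
                })
    return pd.DataFrame(rows, columns=cols)


# ----------------------------------------------------------------------
# direct daily-summary generator (for mixed-model calibration at scale)

def simulate_daily_contact_summaries(
    cfg: SimConfig, n_pairs: int = 16, n_days: int = 70,
    seed: int | None = None,
) -> pd.DataFrame:
    """Daily contact aggregates drawn directly from the contact process,
    bypassing track construction.

    One row per chick-parent pair per day: trials are the day's linked-fix
    count (near the 144 implied by the 10-min cadence, minus dropout) and
    successes are binomial with the logistic age/year/random-effect
    probability.  This is the generative model the contact GLMM assumes,
    at the study's scale, cheap enough for replicated calibration runs.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    cov = np.array([
        [cfg.contact_sd_intercept ** 2,
         cfg.contact_re_corr * cfg.contact_sd_intercept * cfg.contact_sd_slope],
        [cfg.contact_re_corr * cfg.contact_sd_intercept * cfg.contact_sd_slope,
         cfg.contact_sd_slope ** 2]])
    rows = []
    slots_per_day = int(round(24 * 60 / cfg.gps_interval_min))
    for i in range(n_pairs):
        chick_id = f"SC{i:02d}"
        year = cfg.years[i % len(cfg.years)]
        b0, b1 = rng.multivariate_normal([0.0, 0.0], cov)
        chick_sex = rng.choice(["female", "male"])
        parent_sex = rng.choice(["female", "male"])
        start_age = int(rng.integers(35, 41))
        for dday in range(n_days):
            age = start_age + dday
            p = expit(cfg.baseline_contact_odds + b0
                      + (cfg.contact_decay_rate + b1) * (age - 35)
                      + cfg.year_effects.get(year, 0.0))
            n_linked = int(rng.binomial(slots_per_day, (1 - cfg.dropout_rate) ** 2))
            n_contact = int(rng.binomial(n_linked, p))
            n_acc = int(rng.binomial(n_linked, 1 - cfg.acc_missing_rate))
            rows.append({
                "pair_id": f"{chick_id}:{parent_sex}", "chick_id": chick_id,
                "parent_id": f"SP{i:02d}", "date": date(year, 6, 1) + timedelta(days=dday),
                "chick_age": age, "year": year,
                "chick_sex": chick_sex, "parent_sex": parent_sex,
                "n_linked": n_linked, "n_linked_with_acc": n_acc,
                "n_contact": n_contact,
                "n_contact_beg": int(rng.binomial(n_contact, cfg.beg_given_contact)),
                "n_contact_forage": int(rng.binomial(n_contact, 0.3)),
                "p_contact": n_contact / n_linked if n_linked else np.nan,
                "mean_dist_nest_contact_km": float(np.exp(
                    rng.normal(-1.0 + 0.01 * (age - 35), 0.6))) if n_contact else np.nan,
            })
    df = pd.DataFrame(rows)
    df["p_contact_begging"] = df["n_contact_beg"] / df["n_linked_with_acc"]
    df["p_contact_foraging"] = df["n_contact_forage"] / df["n_linked_with_acc"]
    return df


# ----------------------------------------------------------------------
# habitat

def simulate_habitat(cfg: SimConfig):
    """Foraging-habitat polygons (water) around the colony: the sea north
    of the colony island and a freshwater lake to the south-west.
    Returns a list of shapely polygons in lon/lat order."""
    from shapely.geometry import Polygon

    lat0, lon0 = cfg.colony_latlon
    sea = Polygon([
        (lon0 - 1.5, lat0 + 0.01), (lon0 + 1.5, lat0 + 0.01),
        (lon0 + 1.5, lat0 + 1.0), (lon0 - 1.5, lat0 + 1.0)])
    lake = Polygon([
        (lon0 - 0.10, lat0 - 0.05), (lon0 - 0.02, lat0 - 0.05),
        (lon0 - 0.02, lat0 - 0.01), (lon0 - 0.10, lat0 - 0.01)])
    return [sea, lake]
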