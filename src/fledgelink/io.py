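"""Plain-text interchange: CSV for tracks, bursts, feeding records and
summaries; GeoJSON for habitat polygons; JSON for ground truth and run
manifests; YAML for configuration.  Every writer's output round-trips
through its reader."""

from __future__ import annotations

import dataclasses
import json
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .acc import AccSample
from .simulate import SimConfig, TrueItinerary
from .traj import Track

TIME_FMT = "%Y-%m-%dT%H:%M:%S.%f%z"


# ----------------------------------------------------------------------
# tracks

def write_tracks_csv(tracks: Sequence[Track], path) -> None:
    """All birds in one CSV: bird_id, timestamp (ISO-8601 UTC), lat, lon,
    gps_speed_kmh, role."""
    frames = []
    for t in tracks:
        df = t.fixes.copy()
        df.insert(0, "bird_id", t.bird_id)
        df["role"] = t.role
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["timestamp"] = out["timestamp"].dt.strftime(TIME_FMT)
    out.to_csv(path, index=False)


def write_bird_meta_csv(tracks: Sequence[Track], path) -> None:
    rows = [{
        "bird_id": t.bird_id, "role": t.role,
        "colony_lat": t.colony_latlon[0] if t.colony_latlon else np.nan,
        "colony_lon": t.colony_latlon[1] if t.colony_latlon else np.nan,
        "nest_lat": t.nest_latlon[0] if t.nest_latlon else np.nan,
        "nest_lon": t.nest_latlon[1] if t.nest_latlon else np.nan,
    } for t in tracks]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracks_csv(path, meta_path=None) -> list[Track]:
    """Read the track CSV dialect back into Track objects (tolerant of
    extra columns)."""
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    meta = None
    if meta_path is not None and Path(meta_path).exists():
        meta = pd.read_csv(meta_path).set_index("bird_id")
    tracks = []
    for bird_id, grp in df.groupby("bird_id", sort=True):
        colony = nest = None
        role = str(grp["role"].iat[0]) if "role" in grp.columns else ""
        if meta is not None and bird_id in meta.index:
            m = meta.loc[bird_id]
            if np.isfinite(m["colony_lat"]):
                colony = (float(m["colony_lat"]), float(m["colony_lon"]))
            if np.isfinite(m["nest_lat"]):
                nest = (float(m["nest_lat"]), float(m["nest_lon"]))
            role = str(m["role"]) if "role" in m.index else role
        cols = [c for c in ("timestamp", "lat", "lon", "gps_speed_kmh") if c in grp.columns]
        tracks.append(Track(str(bird_id), grp[cols].reset_index(drop=True),
                            colony_latlon=colony, nest_latlon=nest, role=role))
    return tracks


# ----------------------------------------------------------------------
# acceleration bursts (long format)

def write_acc_csv(samples: Iterable[AccSample], path) -> None:
    """Long format: bird_id, burst_start, axis, index, value_g, plus the
    burst-level gps_speed_kmh and annotation repeated per row."""
    axes = ("surge", "sway", "heave")
    rows = []
    for s in samples:
        start = s.burst_start.strftime(TIME_FMT)
        for a, axis in enumerate(axes):
            for i, v in enumerate(s.readings[:, a]):
                rows.append((s.bird_id, start, axis, i, v, s.gps_speed_kmh,
                             s.behaviour if s.behaviour is not None else ""))
    pd.DataFrame(rows, columns=[
        "bird_id", "burst_start", "axis", "index", "value_g",
        "gps_speed_kmh", "behaviour"]).to_csv(path, index=False)


def read_acc_csv(path) -> list[AccSample]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    df["burst_start"] = pd.to_datetime(df["burst_start"], utc=True, format="ISO8601")
    axes = {"surge": 0, "sway": 1, "heave": 2}
    out = []
    for (bird_id, start), grp in df.groupby(["bird_id", "burst_start"], sort=True):
        n = int(grp["index"].max()) + 1
        readings = np.full((n, 3), np.nan)
        for axis, sub in grp.groupby("axis"):
            readings[sub["index"].to_numpy(), axes[axis]] = sub["value_g"].to_numpy()
        beh = grp["behaviour"].iat[0]
        out.append(AccSample(
            bird_id=str(bird_id), burst_start=start, readings=readings,
            gps_speed_kmh=float(grp["gps_speed_kmh"].iat[0]),
            behaviour=str(beh) if beh != "" else None))
    return out


# ----------------------------------------------------------------------
# habitat polygons

def write_habitat_geojson(polygons, path) -> None:
    from shapely.geometry import mapping

    fc = {"type": "FeatureCollection", "features": [
        {"type": "Feature", "properties": {"habitat": "foraging-water"},
         "geometry": mapping(p)} for p in polygons]}
    Path(path).write_text(json.dumps(fc))


def read_habitat_geojson(path) -> list:
    from shapely.geometry import shape

    fc = json.loads(Path(path).read_text())
    return [shape(f["geometry"]) for f in fc["features"]]


# ----------------------------------------------------------------------
# truth / config / manifest

def _jsonify(obj):
    if isinstance(obj, (datetime, pd.Timestamp)):
        return obj.isoformat()
    if isinstance(obj, date):
        return obj.isoformat()
    if isinstance(obj, pd.DataFrame):
        df = obj.copy()
        for c in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[c]):
                df[c] = df[c].map(lambda x: x.isoformat())
            elif df[c].dtype == object:
                df[c] = df[c].map(lambda x: x.isoformat() if isinstance(x, (date, datetime, pd.Timestamp)) else x)
        return df.to_dict(orient="list")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonify(x) for x in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    return obj


def write_truth_json(truths: Sequence[TrueItinerary], path) -> None:
    payload = []
    for t in truths:
        d = dataclasses.asdict(t)
        payload.append(_jsonify(d))
    Path(path).write_text(json.dumps(payload))


def read_truth_json(path) -> list[TrueItinerary]:
    payload = json.loads(Path(path).read_text())
    out = []
    for d in payload:
        for key in ("behaviours", "contacts", "daily_state"):
            if d.get(key) is not None:
                df = pd.DataFrame(d[key])
                if "timestamp" in df.columns:
                    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True,
                                                     format="ISO8601")
                if "date" in df.columns:
                    df["date"] = pd.to_datetime(df["date"]).dt.date
                d[key] = df
        d["hatch_date"] = date.fromisoformat(d["hatch_date"])
        if d.get("departure_day"):
            d["departure_day"] = date.fromisoformat(d["departure_day"])
        if d.get("departure_moment"):
            d["departure_moment"] = pd.Timestamp(d["departure_moment"])
        d["partner_ids"] = tuple(d["partner_ids"])
        out.append(TrueItinerary(**d))
    return out


def load_sim_config(path) -> SimConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "year_effects" in raw:
        raw["year_effects"] = {int(k): float(v) for k, v in raw["year_effects"].items()}
    for key in ("colony_latlon", "departure_age_range", "gsm_interval_h", "years"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SimConfig(**raw)


def save_sim_config(cfg: SimConfig, path) -> None:
    d = _jsonify(dataclasses.asdict(cfg))
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
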