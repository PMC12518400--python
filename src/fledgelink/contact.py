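"""Dyadic chick-parent linkage and contact analysis.

Each chick GPS fix is paired with the temporally nearest parent fix; a
pair is kept when the timestamps are less than 10 min apart, or — at any
time difference — once the parent has departed on migration while the
chick has not (the birds are then certainly not together).  A chick is in
contact when the linked distance is below a threshold (10 m primary, 50 m
sensitivity).  Day-level summaries keep only nearly complete days
(>= 130 linked fixes overall, >= 100 acceleration-complete linked fixes
for behaviour-specific contact) within the 35-136 d age window, and pairs
with >= 10 such days before the chick's departure.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as date_t
from typing import Mapping

import numpy as np
import pandas as pd

from .morpho import AGE_WINDOW_MIN, AGE_WINDOW_MAX
from .traj import Track, DepartureEvent, geodesic_m, geodesic_km

LINKAGE_MAX_DT_MIN = 10.0  # strict: "less than 10 min"
CONTACT_THRESHOLD_M = 10.0  # strict: "less than 10 m"
CONTACT_THRESHOLD_SENSITIVITY_M = 50.0
MIN_LINKED_PER_DAY = 130
MIN_LINKED_ACC_PER_DAY = 100
MIN_DAYS_PER_PAIR = 10
POST_DEPARTURE_RADIUS_KM = 25.0

LINKED_COLUMNS = [
    "pair_id", "chick_id", "parent_id", "chick_ts", "parent_ts",
    "delta_t_min", "distance_m", "in_contact", "parent_departed",
    "chick_lat", "chick_lon", "chick_dist_nest_km",
    "chick_behaviour", "has_acc",
]


def _nearest_indices(chick_ts: np.ndarray, parent_ts: np.ndarray) -> np.ndarray:
    """Index of the temporally nearest parent fix for each chick fix;
    equidistant neighbours resolve to the earlier fix (determinism)."""
    pos = np.searchsorted(parent_ts, chick_ts)
    left = np.clip(pos - 1, 0, len(parent_ts) - 1)
    right = np.clip(pos, 0, len(parent_ts) - 1)
    dl = np.abs(chick_ts - parent_ts[left])
    dr = np.abs(chick_ts - parent_ts[right])
    return np.where(dl <= dr, left, right)  # <= : earlier fix wins ties


def link_tracks(
    chick: Track,
    parent: Track,
    parent_departure: DepartureEvent | pd.Timestamp | None = None,
    chick_departure: DepartureEvent | pd.Timestamp | None = None,
    max_dt_min: float = LINKAGE_MAX_DT_MIN,
) -> pd.DataFrame:
    """Pair every chick fix with the nearest parent fix.

    Rows are retained when |dt| < ``max_dt_min`` minutes, or regardless of
    dt when the parent has already departed (after its departure moment)
    while the chick has not.  Each chick fix links to at most one parent
    fix; one parent fix may serve several chick fixes.  Distances are
    great-circle metres; ``in_contact`` is initialised False (see
    :func:`flag_contact`).
    """
    if len(chick) == 0 or len(parent) == 0:
        raise ValueError("both tracks must be non-empty")

    def _moment(d):
        if d is None:
            return None
        return d.departure_moment if isinstance(d, DepartureEvent) else pd.Timestamp(d)

    p_dep, c_dep = _moment(parent_departure), _moment(chick_departure)
    cts = chick.fixes["timestamp"].astype("int64").to_numpy()
    pts = parent.fixes["timestamp"].astype("int64").to_numpy()
    j = _nearest_indices(cts, pts)
    dt_min = np.abs(cts - pts[j]) / 60e9
    parent_departed = np.zeros(len(cts), dtype=bool)
    if p_dep is not None:
        parent_departed = cts > p_dep.value
        if c_dep is not None:
            parent_departed &= ~(cts > c_dep.value)
    keep = (dt_min < max_dt_min) | parent_departed
    clat = chick.fixes["lat"].to_numpy()[keep]
    clon = chick.fixes["lon"].to_numpy()[keep]
    plat = parent.fixes["lat"].to_numpy()[j[keep]]
    plon = parent.fixes["lon"].to_numpy()[j[keep]]
    out = pd.DataFrame({
        "pair_id": f"{chick.bird_id}:{parent.bird_id}",
        "chick_id": chick.bird_id,
        "parent_id": parent.bird_id,
        "chick_ts": chick.fixes["timestamp"][keep].reset_index(drop=True),
        "parent_ts": parent.fixes["timestamp"].iloc[j[keep]].reset_index(drop=True),
        "delta_t_min": dt_min[keep],
        "distance_m": geodesic_m(clat, clon, plat, plon),
        "in_contact": False,
        "parent_departed": parent_departed[keep],
        "chick_lat": clat,
        "chick_lon": clon,
    })
    if chick.nest_latlon is not None:
        out["chick_dist_nest_km"] = geodesic_km(
            clat, clon, chick.nest_latlon[0], chick.nest_latlon[1])
    else:
        out["chick_dist_nest_km"] = np.nan
    out["chick_behaviour"] = pd.Series([None] * len(out), dtype=object)
    out["has_acc"] = False
    return out


def flag_contact(linked: pd.DataFrame, threshold_m: float = CONTACT_THRESHOLD_M) -> pd.DataFrame:
    """Set ``in_contact`` = (distance < threshold), strict inequality.

    A post-departure linked fix with a large time difference is certain
    non-contact; its (large) distance already guarantees the flag is
    False at any sensible threshold.
    """
    if threshold_m <= 0:
        raise ValueError("contact threshold must be positive")
    out = linked.copy()
    out["in_contact"] = out["distance_m"] < threshold_m
    return out


def attach_behaviour(
    linked: pd.DataFrame,
    behaviour: pd.DataFrame,
    tolerance_s: float = 1.0,
) -> pd.DataFrame:
    """Join classified chick behaviour (timestamp, behaviour[, complete])
    onto linked fixes by exact-or-near timestamp match."""
    beh = behaviour.sort_values("timestamp").copy()
    beh["timestamp"] = pd.to_datetime(beh["timestamp"], utc=True)
    out = linked.sort_values("chick_ts").reset_index(drop=True)
    merged = pd.merge_asof(
        out, beh.rename(columns={"timestamp": "chick_ts", "behaviour": "_beh"}),
        on="chick_ts", direction="nearest",
        tolerance=pd.Timedelta(seconds=tolerance_s))
    out["chick_behaviour"] = merged["_beh"].to_numpy(dtype=object)
    if "complete" in beh.columns:
        out["has_acc"] = merged["complete"].eq(True).to_numpy()
    else:
        out["has_acc"] = out["chick_behaviour"].notna().to_numpy()
    return out


def summarise_daily(
    linked: pd.DataFrame,
    hatch_date: date_t,
    year: int | None = None,
    chick_sex: str | None = None,
    parent_sex: str | None = None,
    min_linked: int = MIN_LINKED_PER_DAY,
    min_linked_acc: int = MIN_LINKED_ACC_PER_DAY,
    age_window: tuple[int, int] = (AGE_WINDOW_MIN, AGE_WINDOW_MAX),
    age_window_first: bool = True,
) -> pd.DataFrame:
    """Per-day contact summaries for one chick-parent pair.

    Days outside the age window are dropped (before the completeness
    filters, by default).  Rows failing the overall filter
    (``n_linked < min_linked``) report NaN for p_contact and the
    nest-distance summaries; rows failing the acceleration filter report
    NaN for the behaviour-specific proportions.  Days failing both are
    excluded entirely.
    """
    df = linked.copy()
    ts = pd.to_datetime(df["chick_ts"], utc=True)
    df["date"] = ts.dt.date
    df["chick_age"] = np.asarray(
        [(d - hatch_date).days for d in df["date"]], dtype=int)
    if age_window_first:
        df = df[(df["chick_age"] >= age_window[0]) & (df["chick_age"] <= age_window[1])]
    rows = []
    for day, grp in df.groupby("date", sort=True):
        n_linked = len(grp)
        acc = grp[grp["has_acc"].astype(bool)]
        n_acc = len(acc)
        ok_overall = n_linked >= min_linked
        ok_behaviour = n_acc >= min_linked_acc
        if not (ok_overall or ok_behaviour):
            continue
        contact = grp[grp["in_contact"]]
        n_contact = len(contact)
        beg = int(((acc["chick_behaviour"] == "beg") & acc["in_contact"]).sum())
        forage = int((acc["chick_behaviour"].isin(["search", "handle", "ingest", "forage"])
                      & acc["in_contact"]).sum())
        rows.append({
            "pair_id": grp["pair_id"].iat[0],
            "chick_id": grp["chick_id"].iat[0],
            "parent_id": grp["parent_id"].iat[0],
            "date": day,
            "chick_age": int(grp["chick_age"].iat[0]),
            "year": year if year is not None else ts.dt.year.iloc[0],
            "chick_sex": chick_sex,
            "parent_sex": parent_sex,
            "n_linked": n_linked,
            "n_linked_with_acc": n_acc,
            "n_contact": n_contact,
            "n_contact_beg": beg,
            "n_contact_forage": forage,
            "ok_overall": ok_overall,
            "ok_behaviour": ok_behaviour,
            "p_contact": n_contact / n_linked if ok_overall else np.nan,
            "p_contact_begging": beg / n_acc if ok_behaviour else np.nan,
            "p_contact_foraging": forage / n_acc if ok_behaviour else np.nan,
            "mean_dist_nest_contact_km":
                float(contact["chick_dist_nest_km"].mean())
                if ok_overall and n_contact else np.nan,
            "median_dist_nest_contact_km":
                float(contact["chick_dist_nest_km"].median())
                if ok_overall and n_contact else np.nan,
        })
    if not age_window_first and rows:
        rows = [r for r in rows
                if age_window[0] <= r["chick_age"] <= age_window[1]]
    return pd.DataFrame(rows)


def pair_filter(
    summaries: pd.DataFrame,
    departures: Mapping[str, date_t] | None = None,
    min_days: int = MIN_DAYS_PER_PAIR,
) -> pd.DataFrame:
    """Retain pairs with >= ``min_days`` nearly complete days, using only
    data strictly before the chick's departure day.

    ``departures`` maps chick_id to its migration departure day; rows on
    or after that day are removed first.
    """
    df = summaries.copy()
    if departures:
        def _pre_departure(row):
            dep = departures.get(row["chick_id"])
            return dep is None or row["date"] < dep
        df = df[df.apply(_pre_departure, axis=1)]
    qualifying = df[df["ok_overall"].astype(bool)] if "ok_overall" in df.columns else df
    days_per_pair = qualifying.groupby("pair_id")["date"].nunique()
    keep = days_per_pair[days_per_pair >= min_days].index
    return df[df["pair_id"].isin(keep)].reset_index(drop=True)


def last_contact_age(linked: pd.DataFrame, hatch_date: date_t) -> int | None:
    """Chick age (days) at the latest in-contact linked fix; None when the
    pair never had contact (distinct from an error)."""
    contact = linked[linked["in_contact"]]
    if contact.empty:
        return None
    last = pd.to_datetime(contact["chick_ts"], utc=True).max()
    return (last.date() - hatch_date).days


def post_departure_proximity(
    chick: Track,
    parent: Track,
    chick_departure: DepartureEvent | pd.Timestamp,
    parent_departure: DepartureEvent | pd.Timestamp,
    radius_km: float = POST_DEPARTURE_RADIUS_KM,
) -> pd.DataFrame:
    """Candidate post-departure meetings for visual review.

    Both birds restricted to fixes after their own departure moments
    (coarse 1-6 h cadence expected); every nearest-fix pair with
    great-circle distance < ``radius_km`` is listed time-ordered with its
    time difference.  Pairs whose tracks never come within the radius
    (the study's non-meeting birds stayed > 40 km apart) yield an empty
    table.
    """
    def _moment(d):
        return d.departure_moment if isinstance(d, DepartureEvent) else pd.Timestamp(d)

    c_dep, p_dep = _moment(chick_departure), _moment(parent_departure)
    cfix = chick.fixes[chick.fixes["timestamp"] >= c_dep].reset_index(drop=True)
    pfix = parent.fixes[parent.fixes["timestamp"] >= p_dep].reset_index(drop=True)
    cols = ["chick_ts", "parent_ts", "delta_t_min", "distance_km"]
    if radius_km <= 0 or cfix.empty or pfix.empty:
        return pd.DataFrame(columns=cols)
    cts = cfix["timestamp"].astype("int64").to_numpy()
    pts = pfix["timestamp"].astype("int64").to_numpy()
    j = _nearest_indices(cts, pts)
    dist = geodesic_km(cfix["lat"].to_numpy(), cfix["lon"].to_numpy(),
                       pfix["lat"].to_numpy()[j], pfix["lon"].to_numpy()[j])
    dt_min = np.abs(cts - pts[j]) / 60e9
    hit = dist < radius_km
    return pd.DataFrame({
        "chick_ts": cfix["timestamp"][hit].reset_index(drop=True),
        "parent_ts": pfix["timestamp"].iloc[j[hit]].reset_index(drop=True),
        "delta_t_min": dt_min[hit], "distance_km": dist[hit],
    }).sort_values("chick_ts").reset_index(drop=True)
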