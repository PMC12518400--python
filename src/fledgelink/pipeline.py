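"""End-to-end pipeline: simulate -> classify -> traj -> contact -> stats.

Writes every intermediate table as CSV, the model-selection tables, a JSON
run manifest (config hash, seed, library versions, per-stage record
counts) and a plain-text summary of the headline results.  Stage failures
abort with the stage name in the error; outputs written so far are kept.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acc as acc_mod
from . import contact as contact_mod
from . import io as io_mod
from . import simulate as sim_mod
from . import stats as stats_mod
from . import traj as traj_mod

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every numeric threshold of the analysis in one place."""

    sim: sim_mod.SimConfig = field(default_factory=sim_mod.SimConfig)
    out_dir: str = "fledgelink-run"
    # contact / linkage
    contact_threshold_m: float = contact_mod.CONTACT_THRESHOLD_M
    linkage_max_dt_min: float = contact_mod.LINKAGE_MAX_DT_MIN
    min_linked: int = contact_mod.MIN_LINKED_PER_DAY
    min_linked_acc: int = contact_mod.MIN_LINKED_ACC_PER_DAY
    min_days: int = contact_mod.MIN_DAYS_PER_PAIR
    age_window: tuple[int, int] = (35, 136)
    age_window_first: bool = True
    # trajectory
    flight_speed_kmh: float = traj_mod.FLIGHT_SPEED_KMH
    departure_travel_km: float = traj_mod.DEPARTURE_DAY_KM
    departure_south_km: float = traj_mod.DEPARTURE_SOUTH_KM
    migratory_net_km: float = traj_mod.MIGRATORY_FLIGHT_NET_KM
    proximity_radius_km: float = contact_mod.POST_DEPARTURE_RADIUS_KM
    southward_metric: str = "geodesic"
    day_offset_hours: float = 0.0
    # classification
    segment_length_s: float = 1.6
    n_train_per_class: int = 200
    # stats
    responses: tuple[str, ...] = ("p_contact",)
    random_effect: str = "chick"
    survival_n_tagged: int = 15
    survival_n_died: int = 7
    survival_ref_rate: float = 0.56
    survival_ref_se: float = 0.04

    def __post_init__(self) -> None:
        for name in ("contact_threshold_m", "linkage_max_dt_min", "min_linked",
                     "min_linked_acc", "min_days", "flight_speed_kmh",
                     "departure_travel_km", "departure_south_km",
                     "migratory_net_km", "proximity_radius_km"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if not self.age_window[0] < self.age_window[1]:
            raise ValueError("age window min must be below max")

    def config_hash(self) -> str:
        """Hash of every output-determining parameter (out_dir excluded:
        where results land does not change what they are)."""
        d = io_mod._jsonify(dataclasses.asdict(self))
        d.pop("out_dir", None)
        return hashlib.sha256(
            yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:16]


class StageError(RuntimeError):
    pass


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


@_stage("simulate")
def _run_simulate(cfg: PipelineConfig, out: Path, counts: dict):
    tracks, truths = sim_mod.simulate_family_tracks(cfg.sim)
    feeding = sim_mod.simulate_feeding_observations(cfg.sim)
    habitat = sim_mod.simulate_habitat(cfg.sim)
    io_mod.write_tracks_csv(tracks, out / "tracks.csv")
    io_mod.write_bird_meta_csv(tracks, out / "birds.csv")
    feeding.to_csv(out / "feeding_observations.csv", index=False)
    io_mod.write_truth_json(truths, out / "truth.json")
    io_mod.write_habitat_geojson(habitat, out / "habitat.geojson")
    counts["simulate"] = {"tracks": len(tracks),
                          "fixes": int(sum(len(t) for t in tracks)),
                          "feeding_records": len(feeding)}
    return tracks, truths, feeding, habitat


@_stage("classify")
def _run_classify(cfg: PipelineConfig, out: Path, truths, counts: dict):
    train = sim_mod.simulate_labelled_bursts(cfg.sim, cfg.n_train_per_class)
    feats, meta = acc_mod.featurize_samples(train, cfg.segment_length_s)
    model = acc_mod.train_classifier(feats, meta["behaviour"], seed=cfg.sim.seed,
                                     segment_length_s=cfg.segment_length_s)
    behaviour_tables: dict[str, pd.DataFrame] = {}
    n_bursts = 0
    for t in truths:
        if t.role != "chick":
            continue
        bursts = sim_mod.simulate_acc_bursts(t, cfg.sim)
        n_bursts += len(bursts)
        complete = [b for b in bursts if b.complete]
        if not complete:
            behaviour_tables[t.bird_id] = pd.DataFrame(
                columns=["timestamp", "behaviour", "complete"])
            continue
        feats_c, meta_c = acc_mod.featurize_samples(complete, cfg.segment_length_s)
        pred = model.predict(feats_c)
        tab = pd.DataFrame({"timestamp": meta_c["burst_start"],
                            "behaviour": pred, "complete": True})
        behaviour_tables[t.bird_id] = tab
    pd.concat(
        [tab.assign(bird_id=bid) for bid, tab in behaviour_tables.items()],
        ignore_index=True,
    ).to_csv(out / "behaviour_classified.csv", index=False)
    counts["classify"] = {"training_segments": len(feats), "chick_bursts": n_bursts}
    return model, behaviour_tables


@_stage("traj")
def _run_traj(cfg: PipelineConfig, out: Path, tracks, counts: dict):
    departures = {}
    rows = []
    for t in tracks:
        day = traj_mod.detect_departure_day(
            t, t.colony_latlon, cfg.departure_travel_km, cfg.departure_south_km,
            southward_metric=cfg.southward_metric,
            day_offset_hours=cfg.day_offset_hours)
        if day is None:
            continue
        try:
            ev = traj_mod.detect_departure_moment(
                t, day, cfg.migratory_net_km, cfg.flight_speed_kmh,
                day_offset_hours=cfg.day_offset_hours)
        except traj_mod.DepartureInconsistencyError as exc:
            logger.warning("%s", exc)
            continue
        departures[t.bird_id] = ev
        rows.append({"bird_id": t.bird_id, "departure_day": day,
                     "departure_moment": ev.departure_moment.isoformat(),
                     "net_km": ev.first_migratory_flight.net_displacement_km})
    pd.DataFrame(rows, columns=["bird_id", "departure_day", "departure_moment",
                                "net_km"]).to_csv(out / "departures.csv", index=False)
    counts["traj"] = {"departures_detected": len(departures)}
    return departures


@_stage("contact")
def _run_contact(cfg: PipelineConfig, out: Path, tracks, truths,
                 behaviour_tables, habitat, departures, counts: dict):
    by_id = {t.bird_id: t for t in tracks}
    truth_by_id = {t.bird_id: t for t in truths}
    summaries = []
    linked_frames = []
    last_ages = []
    proximity_frames = []
    for t in truths:
        if t.role != "chick":
            continue
        chick = by_id[t.bird_id]
        for pid in t.partner_ids:
            parent = by_id[pid]
            linked = contact_mod.link_tracks(
                chick, parent,
                parent_departure=getattr(departures.get(pid), "departure_moment", None),
                chick_departure=getattr(departures.get(t.bird_id), "departure_moment", None),
                max_dt_min=cfg.linkage_max_dt_min)
            linked = contact_mod.attach_behaviour(
                linked, behaviour_tables.get(t.bird_id,
                                             pd.DataFrame(columns=["timestamp", "behaviour"])))
            if habitat is not None and linked["chick_behaviour"].notna().any():
                lab = linked["chick_behaviour"].to_numpy(dtype=object)
                known = linked["chick_behaviour"].notna().to_numpy()
                corrected = acc_mod.habitat_correct(
                    lab[known],
                    linked.loc[known, ["chick_lat", "chick_lon"]].rename(
                        columns={"chick_lat": "lat", "chick_lon": "lon"}),
                    habitat)
                lab[known] = corrected
                linked["chick_behaviour"] = lab
            linked = contact_mod.flag_contact(linked, cfg.contact_threshold_m)
            linked_frames.append(linked)
            daily = contact_mod.summarise_daily(
                linked, t.hatch_date, year=t.year, chick_sex=t.sex,
                parent_sex=truth_by_id[pid].sex,
                min_linked=cfg.min_linked, min_linked_acc=cfg.min_linked_acc,
                age_window=cfg.age_window, age_window_first=cfg.age_window_first)
            if not daily.empty:
                summaries.append(daily)
            age = contact_mod.last_contact_age(linked, t.hatch_date)
            last_ages.append({"pair_id": f"{t.bird_id}:{pid}", "last_contact_age": age})
            if t.bird_id in departures and pid in departures:
                prox = contact_mod.post_departure_proximity(
                    chick, parent, departures[t.bird_id], departures[pid],
                    cfg.proximity_radius_km)
                if not prox.empty:
                    prox.insert(0, "pair_id", f"{t.bird_id}:{pid}")
                    proximity_frames.append(prox)
    linked_all = pd.concat(linked_frames, ignore_index=True) if linked_frames else pd.DataFrame()
    summary_all = pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    dep_days = {bid: ev.departure_day for bid, ev in departures.items()}
    filtered = contact_mod.pair_filter(summary_all, dep_days, cfg.min_days) \
        if not summary_all.empty else summary_all
    linked_all.to_csv(out / "linked_fixes.csv", index=False)
    summary_all.to_csv(out / "daily_contact_all.csv", index=False)
    filtered.to_csv(out / "daily_contact_filtered.csv", index=False)
    pd.DataFrame(last_ages).to_csv(out / "last_contact_age.csv", index=False)
    prox_all = pd.concat(proximity_frames, ignore_index=True) if proximity_frames \
        else pd.DataFrame(columns=["pair_id", "chick_ts", "parent_ts",
                                   "delta_t_min", "distance_km"])
    prox_all.to_csv(out / "post_departure_proximity.csv", index=False)
    counts["contact"] = {
        "linked_fixes": len(linked_all),
        "pair_days": len(summary_all),
        "pair_days_retained": len(filtered),
        "pairs_retained": int(filtered["pair_id"].nunique()) if not filtered.empty else 0,
    }
    return filtered, last_ages, prox_all


@_stage("stats")
def _run_stats(cfg: PipelineConfig, out: Path, feeding, summaries, counts: dict):
    results: dict = {}
    if not feeding.empty and feeding["age_days"].map(
            lambda a: a >= 35).any():
        fc = stats_mod.FeedingCountModel(
            feeding, age_col="age_days").fit(seed=cfg.sim.seed)
        fd = stats_mod.FeedingDistanceModel(
            feeding, age_col="age_days", distance_col="distance_km").fit()
        results["feeding_count"] = fc
        results["feeding_distance"] = fd
    selection_tables = {}
    selected = {}
    if summaries is not None and not summaries.empty:
        for response in cfg.responses:
            fits = stats_mod.candidate_contact_models(
                summaries, response, random=cfg.random_effect)
            if not fits:
                continue
            tab = stats_mod.model_selection_table(fits)
            tab.to_csv(out / f"model_selection_{response}.csv", index=False)
            selection_tables[response] = tab
            selected[response] = stats_mod.select_model(fits)
    surv = stats_mod.survival_comparison(
        cfg.survival_n_tagged, cfg.survival_n_died,
        cfg.survival_ref_rate, cfg.survival_ref_se)
    results.update({"selection_tables": selection_tables,
                    "selected": selected, "survival": surv})
    counts["stats"] = {"responses_modelled": len(selection_tables)}
    return results


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis on simulated inputs; returns the report
    bundle (tables, fitted models, manifest) and writes it under
    ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    tracks, truths, feeding, habitat = _run_simulate(cfg, out, counts)
    model, behaviour_tables = _run_classify(cfg, out, truths, counts)
    departures = _run_traj(cfg, out, tracks, counts)
    summaries, last_ages, proximity = _run_contact(
        cfg, out, tracks, truths, behaviour_tables, habitat, departures, counts)
    stats_results = _run_stats(cfg, out, feeding, summaries, counts)

    import fledgelink

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.sim.seed,
        "versions": {
            "fledgelink": fledgelink.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stage_counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "summary.txt").write_text(_text_summary(cfg, stats_results, last_ages,
                                                   departures, counts))
    return {"manifest": manifest, "stats": stats_results,
            "summaries": summaries, "departures": departures,
            "last_contact_ages": last_ages, "proximity": proximity}


def _text_summary(cfg, stats_results, last_ages, departures, counts) -> str:
    lines = ["fledgelink run summary", "=" * 40]
    if "feeding_count" in stats_results:
        lines += ["", "Feeding observations:",
                  "  " + stats_results["feeding_count"].summary(),
                  "  " + stats_results["feeding_distance"].summary()]
    ages = [a["last_contact_age"] for a in last_ages
            if a["last_contact_age"] is not None]
    if ages:
        lines += ["", "Contact:",
                  f"  last contact at ages {min(ages)}-{max(ages)} d "
                  f"(median {int(np.median(ages))} d) over {len(ages)} pairs"]
    for response, res in stats_results.get("selected", {}).items():
        lines += [f"  most parsimonious {response} model: {res.spec.label} "
                  f"(AICc {res.aicc:.1f}, k={res.k})"]
    if departures:
        lines += ["", "Departure:",
                  f"  {len(departures)} birds departed on autumn migration"]
    surv = stats_results.get("survival")
    if surv is not None:
        lines += ["", "Survival:", "  " + surv.summary()]
    lines += ["", "Stage record counts:", json.dumps(counts, indent=2)]
    return "\n".join(lines) + "\n"
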