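"""Chick-parent linkage, contact flagging, daily summaries and the
post-departure proximity screen."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from fledgelink import contact as cm
from fledgelink.traj import EARTH_RADIUS_KM
from conftest import make_track

KM_PER_DEG_LAT = EARTH_RADIUS_KM * np.pi / 180.0
M_PER_DEG_LAT = KM_PER_DEG_LAT * 1000.0
LAT0, LON0 = 53.4833, 6.25


def track_at_offsets(bird_id, times, north_m, **kwargs):
    lats = [LAT0 + m / M_PER_DEG_LAT for m in north_m]
    return make_track(bird_id, times, lats, [LON0] * len(lats), **kwargs)


class TestLinkTracks:
    def test_small_dt_retained(self):
        chick = track_at_offsets("c", ["2016-07-01 10:00"], [0])
        parent = track_at_offsets("p", ["2016-07-01 10:02"], [5])
        linked = cm.link_tracks(chick, parent)
        assert len(linked) == 1
        assert linked["delta_t_min"].iat[0] == pytest.approx(2.0)
        assert linked["distance_m"].iat[0] == pytest.approx(5.0, abs=0.01)

    def test_dt_over_10min_dropped(self):
        chick = track_at_offsets("c", ["2016-07-01 10:00"], [0])
        parent = track_at_offsets("p", ["2016-07-01 10:11"], [5])
        assert cm.link_tracks(chick, parent).empty

    def test_dt_exactly_10min_dropped(self):
        chick = track_at_offsets("c", ["2016-07-01 10:00"], [0])
        parent = track_at_offsets("p", ["2016-07-01 10:10"], [5])
        assert cm.link_tracks(chick, parent).empty  # strict "less than"

    def test_post_departure_parent_retained_at_any_dt(self):
        chick = track_at_offsets("c", ["2016-09-20 10:00"], [0])
        parent = track_at_offsets("p", ["2016-09-20 13:00"], [-400_000])
        linked = cm.link_tracks(chick, parent,
                                parent_departure=pd.Timestamp("2016-09-15", tz="UTC"))
        assert len(linked) == 1
        assert bool(linked["parent_departed"].iat[0])
        flagged = cm.flag_contact(linked, 10.0)
        assert not flagged["in_contact"].iat[0]

    def test_not_retained_once_chick_departed_too(self):
        chick = track_at_offsets("c", ["2016-09-20 10:00"], [0])
        parent = track_at_offsets("p", ["2016-09-20 13:00"], [-400_000])
        linked = cm.link_tracks(
            chick, parent,
            parent_departure=pd.Timestamp("2016-09-15", tz="UTC"),
            chick_departure=pd.Timestamp("2016-09-18", tz="UTC"))
        assert linked.empty

    def test_tie_resolves_to_earlier_parent_fix(self):
        chick = track_at_offsets("c", ["2016-07-01 10:05"], [0])
        parent = track_at_offsets("p", ["2016-07-01 10:00", "2016-07-01 10:10"],
                                  [3, 8])
        linked = cm.link_tracks(chick, parent)
        assert linked["parent_ts"].iat[0] == pd.Timestamp("2016-07-01 10:00", tz="UTC")

    def test_one_parent_fix_serves_many_chick_fixes(self):
        chick = track_at_offsets(
            "c", ["2016-07-01 10:00", "2016-07-01 10:05", "2016-07-01 10:09"],
            [0, 0, 0])
        parent = track_at_offsets("p", ["2016-07-01 10:04"], [5])
        linked = cm.link_tracks(chick, parent)
        assert len(linked) == 3
        assert linked["parent_ts"].nunique() == 1


class TestFlagContact:
    def make_linked(self, distances):
        chick = track_at_offsets(
            "c", pd.date_range("2016-07-01 10:00", periods=len(distances),
                               freq="10min", tz="UTC"), [0] * len(distances))
        parent = track_at_offsets(
            "p", pd.date_range("2016-07-01 10:01", periods=len(distances),
                               freq="10min", tz="UTC"), distances)
        return cm.link_tracks(chick, parent)

    def test_strict_threshold(self):
        linked = cm.flag_contact(self.make_linked([9.97, 10.03]), 10.0)
        assert list(linked["in_contact"]) == [True, False]

    def test_threshold_monotonicity(self):
        linked = self.make_linked(list(np.linspace(1, 80, 40)))
        n10 = cm.flag_contact(linked, 10.0)["in_contact"].sum()
        n50 = cm.flag_contact(linked, 50.0)["in_contact"].sum()
        assert n50 >= n10

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            cm.flag_contact(self.make_linked([5.0]), 0.0)


def synthetic_linked(n, n_contact, day="2016-07-10", n_acc=None, n_beg=0,
                     n_forage=0, hatch=date(2016, 6, 1), pair="c:p"):
    """Hand-built linked-fix frame: first n_contact fixes in contact; the
    first n_acc fixes carry behaviour labels (n_beg 'beg' then n_forage
    'search', both within the contact block)."""
    ts = pd.date_range(f"{day} 00:00", periods=n, freq="9min", tz="UTC")
    in_contact = np.zeros(n, dtype=bool)
    in_contact[:n_contact] = True
    beh = np.array([None] * n, dtype=object)
    has_acc = np.zeros(n, dtype=bool)
    if n_acc:
        has_acc[:n_acc] = True
        beh[:n_acc] = "stand"
        beh[:n_beg] = "beg"
        beh[n_beg:n_beg + n_forage] = "search"
    return pd.DataFrame({
        "pair_id": pair, "chick_id": pair.split(":")[0],
        "parent_id": pair.split(":")[1],
        "chick_ts": ts, "parent_ts": ts, "delta_t_min": 0.5,
        "distance_m": np.where(in_contact, 5.0, 100.0),
        "in_contact": in_contact, "parent_departed": False,
        "chick_lat": LAT0, "chick_lon": LON0,
        "chick_dist_nest_km": 1.0,
        "chick_behaviour": beh, "has_acc": has_acc,
    })


class TestSummariseDaily:
    def test_proportion_arithmetic(self):
        daily = cm.summarise_daily(synthetic_linked(144, 72), date(2016, 6, 1))
        assert len(daily) == 1
        assert daily["p_contact"].iat[0] == pytest.approx(0.5)
        assert daily["chick_age"].iat[0] == 39

    def test_129_linked_fixes_fails_overall_filter(self):
        daily = cm.summarise_daily(synthetic_linked(129, 60, n_acc=110),
                                   date(2016, 6, 1))
        # still present for behaviour-specific output, but overall is NaN
        assert len(daily) == 1
        assert not daily["ok_overall"].iat[0]
        assert np.isnan(daily["p_contact"].iat[0])
        assert daily["ok_behaviour"].iat[0]

    def test_begging_proportion(self):
        daily = cm.summarise_daily(
            synthetic_linked(144, 40, n_acc=100, n_beg=10), date(2016, 6, 1))
        assert daily["p_contact_begging"].iat[0] == pytest.approx(0.10)

    def test_foraging_contact_proportion(self):
        daily = cm.summarise_daily(
            synthetic_linked(144, 40, n_acc=100, n_beg=5, n_forage=20),
            date(2016, 6, 1))
        assert daily["p_contact_foraging"].iat[0] == pytest.approx(0.20)

    def test_age_window_applied(self):
        # chick only 20 d old on this day: outside the 35-136 d window
        daily = cm.summarise_daily(synthetic_linked(144, 10), date(2016, 6, 20))
        assert daily.empty

    def test_day_below_both_filters_absent(self):
        daily = cm.summarise_daily(synthetic_linked(50, 10, n_acc=40),
                                   date(2016, 6, 1))
        assert daily.empty

    def test_brute_force_recount(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            n = int(rng.integers(130, 160))
            k = int(rng.integers(0, n))
            daily = cm.summarise_daily(synthetic_linked(n, k), date(2016, 6, 1))
            assert daily["p_contact"].iat[0] == pytest.approx(k / n)
            assert daily["n_contact"].iat[0] == k


class TestPairFilter:
    def frame(self, pair, n_days, start="2016-07-10"):
        days = pd.date_range(start, periods=n_days, freq="D")
        return pd.DataFrame({
            "pair_id": pair, "chick_id": pair.split(":")[0],
            "date": days.date, "ok_overall": True,
            "chick_age": range(40, 40 + n_days),
        })

    def test_pair_below_min_days_removed(self):
        df = pd.concat([self.frame("a:p", 9), self.frame("b:p", 10)])
        out = cm.pair_filter(df)
        assert set(out["pair_id"]) == {"b:p"}

    def test_rows_on_after_departure_removed(self):
        df = self.frame("a:p", 15)
        out = cm.pair_filter(df, departures={"a": date(2016, 7, 20)}, min_days=5)
        assert out["date"].max() < date(2016, 7, 20)

    def test_departure_can_disqualify_pair(self):
        df = self.frame("a:p", 15)
        out = cm.pair_filter(df, departures={"a": date(2016, 7, 15)}, min_days=10)
        assert out.empty  # only 5 pre-departure days remain


class TestLastContactAge:
    def test_single_contact(self):
        linked = synthetic_linked(144, 1, day="2016-07-21")  # age 50
        assert cm.last_contact_age(linked, date(2016, 6, 1)) == 50

    def test_latest_of_many(self):
        frames = [synthetic_linked(144, 1, day=d) for d in
                  ("2016-07-11", "2016-08-28", "2016-09-29")]
        linked = pd.concat(frames, ignore_index=True)
        assert cm.last_contact_age(linked, date(2016, 6, 1)) == 120

    def test_no_contact_is_none(self):
        linked = synthetic_linked(144, 0)
        assert cm.last_contact_age(linked, date(2016, 6, 1)) is None


class TestPostDepartureProximity:
    def test_distant_parallel_tracks_empty(self):
        times = pd.date_range("2016-09-20", periods=10, freq="3h", tz="UTC")
        chick = track_at_offsets("c", times, [-i * 50_000 for i in range(10)])
        parent = make_track("p", times, [LAT0 - i * 50_000 / M_PER_DEG_LAT
                                         for i in range(10)],
                            [LON0 + 0.9] * 10)  # always ~60 km east
        out = cm.post_departure_proximity(chick, parent, times[0], times[0])
        assert out.empty

    def test_joint_flock_contiguous_run(self):
        times_c = pd.date_range("2016-09-20", periods=12, freq="1h", tz="UTC")
        times_p = times_c + pd.Timedelta(minutes=4)
        south = [-i * 45_000 for i in range(12)]
        chick = track_at_offsets("c", times_c, south)
        parent = track_at_offsets("p", times_p, south)
        out = cm.post_departure_proximity(chick, parent, times_c[0], times_c[0])
        assert len(out) == 12
        assert (out["delta_t_min"] <= 4.0 + 1e-9).all()
        assert (out["distance_km"] < 25.0).all()

    def test_zero_radius_empty(self):
        times = pd.date_range("2016-09-20", periods=3, freq="2h", tz="UTC")
        chick = track_at_offsets("c", times, [0, -50_000, -100_000])
        out = cm.post_departure_proximity(chick, chick, times[0], times[0],
                                          radius_km=0.0)
        assert out.empty


class TestSimulatorRecovery:
    """Injected contact episodes are recovered through linkage + flagging."""

    def test_episode_detection_and_monotonicity(self, small_config, small_family_data):
        tracks, truths = small_family_data
        detected, total = 0, 0
        for t in truths.values():
            if t.role != "chick":
                continue
            for pid in t.partner_ids:
                linked = cm.link_tracks(tracks[t.bird_id], tracks[pid])
                linked10 = cm.flag_contact(linked, 10.0)
                linked50 = cm.flag_contact(linked, 50.0)
                truth = t.contacts[t.contacts["partner_id"] == pid]
                m = linked10.merge(truth, left_on="chick_ts", right_on="timestamp")
                sub = m[(m["delta_t_min"] < 1.0) & m["in_contact_y"]]
                total += len(sub)
                detected += int(sub["in_contact_x"].sum())
                # per-day threshold monotonicity
                daily10 = cm.summarise_daily(linked10, t.hatch_date, min_linked=1)
                daily50 = cm.summarise_daily(linked50, t.hatch_date, min_linked=1)
                joined = daily10.merge(daily50, on="date")
                assert (joined["p_contact_y"] >= joined["p_contact_x"] - 1e-12).all()
        assert total > 100
        assert detected / total >= 0.99
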