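"""Acceleration segmentation, features, F-measure, classifier and the
habitat correction of foraging labels."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon
from sklearn.metrics import f1_score

from fledgelink import acc
from fledgelink.simulate import SimConfig, simulate_labelled_bursts

T0 = pd.Timestamp("2016-07-01 12:00", tz="UTC")


def burst(n=32, fill=0.0, speed=0.0, behaviour=None):
    return acc.AccSample("b", T0, np.full((n, 3), fill), speed, behaviour)


class TestSegmentation:
    @pytest.mark.parametrize("length,expected", [(0.4, 4), (0.8, 2), (1.6, 1)])
    def test_full_burst_counts(self, length, expected):
        segs = acc.segment_bursts([burst()], length)
        assert len(segs) == expected
        assert all(s.readings.shape[0] == int(length * 20) for s in segs)

    def test_truncated_burst_keeps_full_segments_only(self):
        # 1.2 s at 20 Hz = 24 samples: one 0.8 s segment, 0.4 s discarded
        segs = acc.segment_bursts([burst(n=24)], 0.8)
        assert len(segs) == 1

    def test_truncated_burst_not_complete(self):
        assert not burst(n=24).complete
        assert burst(n=32).complete

    def test_unsupported_length_rejected(self):
        with pytest.raises(ValueError):
            acc.segment_bursts([burst()], 1.0)


class TestFeaturize:
    def test_constant_segment_zero_dynamics(self):
        f = pd.Series(acc.featurize(np.zeros((32, 3)), 0.0),
                      index=acc.feature_names())
        assert f["surge_sd"] == 0.0 and f["heave_sd"] == 0.0
        assert f["odba"] == 0.0
        assert f["surge_domfreq_hz"] == 0.0

    def test_pure_sinusoid_dominant_frequency(self):
        t = np.arange(32) / 20.0
        seg = np.zeros((32, 3))
        seg[:, 2] = np.sin(2 * np.pi * 2.0 * t)  # 2 Hz on heave
        f = pd.Series(acc.featurize(seg, 0.0), index=acc.feature_names())
        # zero-padded spectrum: grid of 20/256 Hz plus leakage bias
        assert f["heave_domfreq_hz"] == pytest.approx(2.0, abs=0.1)

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        seg = rng.normal(size=(32, 3))
        np.testing.assert_array_equal(acc.featurize(seg, 3.0), acc.featurize(seg, 3.0))

    def test_shift_invariance_except_location_features(self):
        rng = np.random.default_rng(2)
        seg = rng.normal(size=(32, 3))
        names = acc.feature_names()
        f0 = pd.Series(acc.featurize(seg, 3.0), index=names)
        f1 = pd.Series(acc.featurize(seg + 0.7, 3.0), index=names)
        location = [n for n in names if n.endswith(("_mean", "_min", "_max"))]
        invariant = [n for n in names if n not in location]
        np.testing.assert_allclose(f0[invariant], f1[invariant], atol=1e-9)
        assert not np.allclose(f0[location], f1[location])

    def test_nonfinite_rejected(self):
        seg = np.zeros((32, 3))
        seg[3, 1] = np.nan
        with pytest.raises(ValueError):
            acc.featurize(seg, 0.0)


class TestFMeasure:
    def test_hand_counted_confusion(self):
        # TP=8, FP=2, FN=2 for class 'a'
        truth = ["a"] * 10 + ["b"] * 10
        pred = ["a"] * 8 + ["b"] * 2 + ["a"] * 2 + ["b"] * 8
        f = acc.f_measure(pred, truth, pooling={})
        assert f["a"] == pytest.approx(0.8)

    def test_perfect_prediction(self):
        labels = ["beg", "walk", "sit", "search"] * 5
        f = acc.f_measure(labels, labels)
        assert all(v == 1.0 for v in f.values())

    def test_pooling_absorbs_within_group_confusion(self):
        truth = ["search"] * 10
        pred = ["ingest"] * 10  # wrong class, same pooled group
        f = acc.f_measure(pred, truth)
        assert f["forage"] == 1.0

    def test_absent_class_scores_zero(self):
        f = acc.f_measure(["walk", "walk"], ["beg", "beg"], pooling={})
        assert f["beg"] == 0.0 and f["walk"] == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            acc.f_measure(["a"], ["a", "b"])

    def test_matches_sklearn_on_random_sequences(self):
        rng = np.random.default_rng(3)
        classes = list(acc.BEHAVIOUR_CLASSES)
        for _ in range(1000):
            n = rng.integers(5, 60)
            truth = rng.choice(classes, n)
            pred = rng.choice(classes, n)
            mine = acc.f_measure(pred, truth, pooling={})
            pooled_classes = sorted(set(truth) | set(pred))
            ref = f1_score(truth, pred, labels=pooled_classes,
                           average=None, zero_division=0)
            for cls, r in zip(pooled_classes, ref):
                assert mine[cls] == pytest.approx(r, abs=1e-12)


class TestClassifier:
    def test_noise_free_world_perfectly_separable(self):
        cfg = SimConfig(seed=5, acc_noise=0.0)
        samples = simulate_labelled_bursts(cfg, n_per_class=20, seed=5)
        scores = acc.evaluate_classifier(samples, 1.6, seed=5, n_estimators=50)
        assert all(v == 1.0 for v in scores.values())

    def test_noise_free_nearest_centroid(self):
        from sklearn.neighbors import NearestCentroid
        from sklearn.preprocessing import StandardScaler

        cfg = SimConfig(seed=6, acc_noise=0.0)
        samples = simulate_labelled_bursts(cfg, n_per_class=20, seed=6)
        feats, meta = acc.featurize_samples(samples, 1.6)
        X = StandardScaler().fit_transform(feats.drop(columns="segment_length_s"))
        y = meta["behaviour"]
        pred = NearestCentroid().fit(X, y).predict(X)
        assert (pred == y).all()

    def test_begging_f_improves_with_segment_length(self):
        # begging is a 1.4 Hz display: short segments cannot resolve it
        cfg = SimConfig(seed=7)
        samples = simulate_labelled_bursts(cfg, n_per_class=250, seed=7)
        f_short = acc.evaluate_classifier(samples, 0.4, seed=7, n_estimators=150)
        f_long = acc.evaluate_classifier(samples, 1.6, seed=7, n_estimators=150)
        assert f_long["beg"] >= f_short["beg"]

    def test_shuffled_labels_near_prevalence(self):
        cfg = SimConfig(seed=8)
        samples = simulate_labelled_bursts(
            cfg, n_per_class=40, seed=8,
            classes=("sit", "fly-active", "beg", "walk"))
        feats, meta = acc.featurize_samples(samples, 1.6)
        rng = np.random.default_rng(8)
        y = rng.permutation(meta["behaviour"].to_numpy())
        X_tr, X_te, y_tr, y_te = acc.stratified_split(feats, y, seed=8)
        model = acc.train_classifier(X_tr, y_tr, seed=8, n_estimators=100)
        f = acc.f_measure(model.predict(X_te), y_te, pooling={})
        # four balanced classes: chance-level F is around 0.25
        assert np.mean(list(f.values())) < 0.5

    def test_degenerate_training_rejected(self):
        feats = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)),
                             columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            acc.train_classifier(feats, ["sit"] * 10)
        with pytest.raises(ValueError, match="fewer than"):
            acc.train_classifier(feats, ["sit"] * 8 + ["beg"] * 2)


class TestHabitatCorrect:
    water = [Polygon([(6.0, 53.0), (6.5, 53.0), (6.5, 53.5), (6.0, 53.5)])]

    def fixes(self, lat, lon, n=1):
        return pd.DataFrame({"lat": [lat] * n, "lon": [lon] * n})

    def test_forage_over_water_unchanged(self):
        out = acc.habitat_correct(["search"], self.fixes(53.2, 6.2), self.water)
        assert list(out) == ["search"]

    def test_forage_over_land_becomes_walk(self):
        out = acc.habitat_correct(["search", "ingest"],
                                  self.fixes(52.0, 5.0, 2), self.water)
        assert list(out) == ["walk", "walk"]

    def test_non_forage_labels_untouched(self):
        out = acc.habitat_correct(["beg", "sit", "fly-active"],
                                  self.fixes(52.0, 5.0, 3), self.water)
        assert list(out) == ["beg", "sit", "fly-active"]

    def test_outside_coverage_configurable(self):
        out = acc.habitat_correct(["search"], self.fixes(10.0, 10.0), self.water,
                                  outside_coverage="water")
        assert list(out) == ["search"]
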