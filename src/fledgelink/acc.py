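"""Accelerometer behaviour classification.

Tri-axial 20 Hz bursts (1.6 s) paired with GPS fixes are cut into
fixed-length segments (0.4, 0.8 or 1.6 s), summarised into per-axis and
cross-axis statistics plus GPS speed, and classified into nine behaviour
classes with a random forest.  The chick-specific class 'beg' (rhythmic
head pumping at a parent) is included alongside the adult repertoire.
Evaluation uses the per-class F-measure with pooled super-classes
(forage, rest, fly), and a habitat rule rewrites foraging classified on
land to walking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

ACC_RATE_HZ = 20.0
BURST_LEN_S = 1.6
SEGMENT_LENGTHS_S = (0.4, 0.8, 1.6)

BEHAVIOUR_CLASSES = (
    "search", "handle", "ingest", "sit", "stand",
    "fly-active", "fly-passive", "walk", "beg",
)

#: Default pooling used for evaluation: within-group confusion is ignored.
DEFAULT_POOLING: dict[str, str] = {
    "search": "forage", "handle": "forage", "ingest": "forage",
    "sit": "rest", "stand": "rest",
    "fly-active": "fly", "fly-passive": "fly",
    "walk": "walk", "beg": "beg",
}

FORAGE_CLASSES = frozenset({"search", "handle", "ingest", "forage"})

AXES = ("surge", "sway", "heave")


@dataclass
class AccSample:
    """One acceleration burst: readings of shape (n_samples, 3) in g,
    paired with the GPS fix's logger speed."""

    bird_id: str
    burst_start: pd.Timestamp
    readings: np.ndarray  # (n, 3): surge, sway, heave
    gps_speed_kmh: float
    behaviour: str | None = None  # annotation, if any
    rate_hz: float = ACC_RATE_HZ

    def __post_init__(self) -> None:
        self.readings = np.asarray(self.readings, dtype=float)
        if self.readings.ndim != 2 or self.readings.shape[1] != 3:
            raise ValueError("readings must have shape (n, 3)")

    @property
    def complete(self) -> bool:
        """True iff the full 1.6 s at 20 Hz is present."""
        return self.readings.shape[0] >= int(round(BURST_LEN_S * self.rate_hz))


def segment_bursts(
    samples: Iterable[AccSample], segment_length_s: float
) -> list[AccSample]:
    """Cut bursts into non-overlapping fixed-length segments.

    Only full segments are kept: a trailing remainder shorter than the
    segment length, and hence any burst shorter than one segment, is
    discarded.  Incomplete (truncated) bursts contribute the full segments
    they contain.
    """
    if segment_length_s not in SEGMENT_LENGTHS_S:
        raise ValueError(
            f"segment length must be one of {SEGMENT_LENGTHS_S} s, got {segment_length_s}"
        )
    out: list[AccSample] = []
    for s in samples:
        npts = int(round(segment_length_s * s.rate_hz))
        nseg = s.readings.shape[0] // npts
        for k in range(nseg):
            out.append(AccSample(
                bird_id=s.bird_id,
                burst_start=s.burst_start + pd.Timedelta(seconds=k * segment_length_s),
                readings=s.readings[k * npts:(k + 1) * npts],
                gps_speed_kmh=s.gps_speed_kmh,
                behaviour=s.behaviour,
                rate_hz=s.rate_hz,
            ))
    return out


def feature_names() -> list[str]:
    names: list[str] = []
    for ax in AXES:
        names += [f"{ax}_{stat}" for stat in
                  ("mean", "sd", "min", "max", "skew", "kurtosis", "domfreq_hz", "dompower")]
    names += ["corr_surge_sway", "corr_surge_heave", "corr_sway_heave", "odba", "gps_speed_kmh"]
    return names


_NFFT = 256  # zero-padded: 0.078 Hz grid at 20 Hz, finer than any segment


def _dominant_frequency(x: np.ndarray, rate_hz: float) -> tuple[float, float]:
    """Dominant spectral frequency (Hz) and its power, from the
    zero-padded DFT of the mean-detrended signal.  Zero signal -> (0, 0)."""
    xd = x - x.mean()
    if np.allclose(xd, 0.0):
        return 0.0, 0.0
    power = np.abs(np.fft.rfft(xd, _NFFT)) ** 2 / len(x)
    power[0] = 0.0  # DC removed by detrending anyway
    k = int(power.argmax())
    return k * rate_hz / _NFFT, float(power[k])


def _moments(x: np.ndarray) -> tuple[float, float, float, float, float, float]:
    m, sd = float(x.mean()), float(x.std())
    if sd == 0.0:
        skew = kurt = 0.0
    else:
        z = (x - m) / sd
        skew, kurt = float(np.mean(z ** 3)), float(np.mean(z ** 4))
    return m, sd, float(x.min()), float(x.max()), skew, kurt


def featurize(segment: np.ndarray, gps_speed_kmh: float, rate_hz: float = ACC_RATE_HZ) -> np.ndarray:
    """Summary-statistic feature vector for one full segment.

    Per axis: mean, SD, min, max, skewness, kurtosis, dominant spectral
    frequency and its power; plus pairwise axis correlations, ODBA (overall
    dynamic body acceleration: mean summed |deviation from axis mean|) and
    the GPS speed.  All features except the per-axis means, min and max are
    invariant to adding a constant to all three axes.
    """
    segment = np.asarray(segment, dtype=float)
    if not np.all(np.isfinite(segment)) or not np.isfinite(gps_speed_kmh):
        raise ValueError("non-finite acceleration readings or GPS speed")
    feats: list[float] = []
    for a in range(3):
        x = segment[:, a]
        feats.extend(_moments(x))
        feats.extend(_dominant_frequency(x, rate_hz))
    sds = segment.std(axis=0)
    centred = segment - segment.mean(axis=0)
    for i, j in ((0, 1), (0, 2), (1, 2)):
        if sds[i] == 0.0 or sds[j] == 0.0:
            feats.append(0.0)
        else:
            feats.append(float(np.mean(centred[:, i] * centred[:, j]) / (sds[i] * sds[j])))
    odba = float(np.mean(np.sum(np.abs(centred), axis=1)))
    feats.append(odba)
    feats.append(float(gps_speed_kmh))
    return np.asarray(feats)


def featurize_samples(
    samples: Sequence[AccSample], segment_length_s: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment bursts and featurize every full segment.

    Returns (features, meta) with aligned rows; meta carries bird_id,
    burst_start and the annotated behaviour (if any).
    """
    segs = segment_bursts(samples, segment_length_s)
    X = np.empty((len(segs), len(feature_names())))
    meta = []
    for i, s in enumerate(segs):
        X[i] = featurize(s.readings, s.gps_speed_kmh, s.rate_hz)
        meta.append((s.bird_id, s.burst_start, s.behaviour))
    features = pd.DataFrame(X, columns=feature_names())
    features["segment_length_s"] = segment_length_s
    return features, pd.DataFrame(meta, columns=["bird_id", "burst_start", "behaviour"])


@dataclass
class ClassifierModel:
    """Random-forest behaviour classifier with its training metadata."""

    forest: RandomForestClassifier
    feature_names: list[str]
    classes: list[str]
    segment_length_s: float
    seed: int

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.forest.predict(features[self.feature_names])

    def predict_proba(self, features: pd.DataFrame) -> pd.DataFrame:
        p = self.forest.predict_proba(features[self.feature_names])
        return pd.DataFrame(p, columns=self.forest.classes_)

    @property
    def feature_importances(self) -> pd.Series:
        return pd.Series(self.forest.feature_importances_, index=self.feature_names)


def train_classifier(
    features: pd.DataFrame,
    labels: Sequence[str],
    seed: int = 0,
    n_estimators: int = 200,
    class_weight: str | None = "balanced",
    segment_length_s: float = BURST_LEN_S,
    min_per_class: int = 5,
) -> ClassifierModel:
    """Fit the ensemble behaviour classifier.

    Begging is rare in annotated material, so trees are class-weight
    balanced by default.  Requires >= 2 classes with at least
    ``min_per_class`` segments each.
    """
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise ValueError("training requires at least 2 behaviour classes")
    if (counts < min_per_class).any():
        starved = counts[counts < min_per_class].index.tolist()
        raise ValueError(f"classes with fewer than {min_per_class} segments: {starved}")
    cols = [c for c in features.columns if c != "segment_length_s"]
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, class_weight=class_weight, n_jobs=1,
    )
    forest.fit(features[cols], labels)
    return ClassifierModel(forest, cols, sorted(counts.index), segment_length_s, seed)


def stratified_split(
    features: pd.DataFrame, labels: Sequence[str], test_size: float = 0.3, seed: int = 0
):
    """Stratified train/test split (wrapper kept for a stable protocol)."""
    return train_test_split(
        features, np.asarray(labels), test_size=test_size, random_state=seed,
        stratify=np.asarray(labels),
    )


def pool_labels(labels: Sequence[str], pooling: Mapping[str, str] | None) -> np.ndarray:
    pooling = DEFAULT_POOLING if pooling is None else pooling
    return np.asarray([pooling.get(l, l) for l in labels])


def f_measure(
    pred: Sequence[str], truth: Sequence[str],
    pooling: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Per-class F-measure (harmonic mean of precision and recall).

    Pooling is applied to both predictions and truth before scoring, so
    confusion within a pooled group does not count against it.  A class
    with precision + recall = 0 scores F = 0.
    """
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    p = pool_labels(pred, pooling)
    t = pool_labels(truth, pooling)
    scores: dict[str, float] = {}
    for cls in np.unique(np.concatenate([p, t])):
        tp = int(np.sum((p == cls) & (t == cls)))
        fp = int(np.sum((p == cls) & (t != cls)))
        fn = int(np.sum((p != cls) & (t == cls)))
        denom = 2 * tp + fp + fn
        scores[str(cls)] = 2 * tp / denom if denom else 0.0
    return scores


def evaluate_classifier(
    samples: Sequence[AccSample],
    segment_length_s: float,
    seed: int = 0,
    test_size: float = 0.3,
    pooling: Mapping[str, str] | None = None,
    **train_kwargs,
) -> dict[str, float]:
    """Train on a stratified split of annotated bursts and return held-out
    per-(pooled-)class F-measures."""
    feats, meta = featurize_samples(samples, segment_length_s)
    labelled = meta["behaviour"].notna().to_numpy()
    X, y = feats[labelled], meta.loc[labelled, "behaviour"].to_numpy()
    X_tr, X_te, y_tr, y_te = stratified_split(X, y, test_size=test_size, seed=seed)
    model = train_classifier(X_tr, y_tr, seed=seed,
                             segment_length_s=segment_length_s, **train_kwargs)
    return f_measure(model.predict(X_te), y_te, pooling=pooling)


def habitat_correct(
    labels: Sequence[str],
    fixes: pd.DataFrame,
    habitat_polygons,
    outside_coverage: str = "land",
) -> np.ndarray:
    """Rewrite foraging classified outside foraging habitat to walking.

    A bird can only truly forage in water (freshwater, brackish or marine
    habitat); forage-class labels at fixes on land become 'walk'.  Other
    labels are never touched.  ``habitat_polygons`` is an iterable of
    shapely geometries covering foraging habitat (lon/lat order).  Fixes
    outside map coverage are treated as land by default.
    """
    from shapely.geometry import Point
    from shapely.prepared import prep

    if outside_coverage not in ("land", "water"):
        raise ValueError("outside_coverage must be 'land' or 'water'")
    prepared = [prep(g) for g in habitat_polygons]
    labels = np.asarray(labels, dtype=object)
    out = labels.copy()
    lats, lons = fixes["lat"].to_numpy(), fixes["lon"].to_numpy()
    for i, lab in enumerate(labels):
        if lab not in FORAGE_CLASSES:
            continue
        pt = Point(lons[i], lats[i])
        in_water = any(g.covers(pt) for g in prepared)
        if not in_water and outside_coverage == "land":
            out[i] = "walk"
    return out
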