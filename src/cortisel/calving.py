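"""Calving-date estimation from recursive movement.

Elk calves hide for ~5 days after birth and their mothers stay close,
producing a distinctive movement signature: many re-entries into a small
neighbourhood, short steps, and low net displacement.  The detector counts
revisits within a 300-m buffer around every GPS fix, trains a random-forest
classifier on fixes inside/outside observed 5-day calving events (classes
balanced by down-sampling), derives a probability threshold from the fixes
inside observed events, and then scans unobserved tracks with a 5-day rolling
window, repeating the train/score cycle 100 times and averaging per-fix
probabilities.  The estimated calving date is the first date of the best
above-threshold window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np

from .synthetic import CalvingEvent, Track

DAY = np.timedelta64(86400, "s")
HOUR = np.timedelta64(3600, "s")


@dataclass
class DetectorConfig:
    radius: float = 300.0  # metres
    event_length: float = 5.0  # days
    season_window: tuple[tuple[int, int], tuple[int, int]] = ((5, 15), (7, 20))
    n_repeats: int = 100
    n_trees: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.event_length < 1:
            raise ValueError("event length must be at least 1 day")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")


@dataclass
class RecursionRecord:
    individual_id: str
    revisits: np.ndarray  # per fix: number of distinct entries into its buffer


@dataclass
class CalvingPrediction:
    individual_id: str
    window_start: date
    window_end: date
    mean_prob: float
    date_range_days: float  # across-repeat range of best first-dates
    date_se_days: float

    @property
    def calving_date(self) -> date:
        """The first date within the calving-event window."""
        return self.window_start


# ---------------------------------------------------------------------------
# recursion analysis
# ---------------------------------------------------------------------------

def count_revisits(track: Track, radius: float = 300.0) -> RecursionRecord:
    """Number of distinct visits to the circle of radius ``radius`` centred
    on each fix: maximal time-contiguous runs of fixes within the circle.

    The run containing the focal fix itself counts, so every count is >= 1.
    """
    if len(track) < 2:
        raise ValueError("need at least 2 fixes")
    x, y = track.x, track.y
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite coordinates")
    n = len(x)
    counts = np.empty(n, dtype=int)
    chunk = max(1, int(4e6 // n))
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        d2 = (x[s:e, None] - x[None, :]) ** 2 + (y[s:e, None] - y[None, :]) ** 2
        inside = d2 <= radius**2
        entries = inside[:, 0].astype(int) + (inside[:, 1:] & ~inside[:, :-1]).sum(axis=1)
        counts[s:e] = entries
    return RecursionRecord(track.individual_id, counts)


# ---------------------------------------------------------------------------
# per-fix features
# ---------------------------------------------------------------------------

def fix_features(track: Track, config: DetectorConfig) -> np.ndarray:
    """Per-fix feature matrix: revisit count (300 m), mean step length and
    net displacement in a centred 24-h window, and hour of day."""
    rev = count_revisits(track, config.radius).revisits.astype(float)
    t = track.t
    n = len(t)
    step_len = np.hypot(np.diff(track.x), np.diff(track.y))
    cs = np.concatenate([[0.0], np.cumsum(step_len)])
    lo = np.searchsorted(t, t - 12 * HOUR, side="left")
    hi = np.minimum(np.searchsorted(t, t + 12 * HOUR, side="right") - 1, n - 1)
    nsteps = np.maximum(hi - lo, 1)
    mean_step = (cs[hi] - cs[lo]) / nsteps
    net_disp = np.hypot(track.x[hi] - track.x[lo], track.y[hi] - track.y[lo])
    hour = (t - t.astype("datetime64[D]")).astype("timedelta64[s]").astype(float) / 3600.0
    return np.column_stack([rev, mean_step, net_disp, hour])


def season_mask(track: Track, config: DetectorConfig) -> np.ndarray:
    """Fixes falling inside the detection season window of their own year."""
    years = track.t.astype("datetime64[Y]").astype(int) + 1970
    m = np.zeros(len(track), dtype=bool)
    (m0, d0), (m1, d1) = config.season_window
    for y in np.unique(years):
        lo = np.datetime64(f"{y:04d}-{m0:02d}-{d0:02d}", "s")
        hi = np.datetime64(f"{y:04d}-{m1:02d}-{d1:02d}", "s") + DAY
        m |= (track.t >= lo) & (track.t < hi)
    return m


def event_labels(track: Track, event: CalvingEvent, config: DetectorConfig) -> np.ndarray:
    """1 for fixes inside [calving_date, calving_date + event_length days]."""
    lo = np.datetime64(event.calving_date.isoformat(), "s")
    hi = lo + np.timedelta64(int(config.event_length * 86400), "s")
    return ((track.t >= lo) & (track.t <= hi)).astype(int)


# ---------------------------------------------------------------------------
# classifier contract
# ---------------------------------------------------------------------------

class RandomForestClassifierAdapter:
    """Default classifier: sklearn random forest behind the pluggable
    fit/predict_prob contract."""

    def __init__(self, n_trees: int = 100, seed: int = 0):
        from sklearn.ensemble import RandomForestClassifier

        self._m = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(seed) % 2**31, n_jobs=1,
            oob_score=True,
        )

    def fit(self, features: np.ndarray, labels: np.ndarray) -> None:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # rows never left out-of-bag
            self._m.fit(features, labels)

    def predict_prob(self, features: np.ndarray) -> np.ndarray:
        proba = self._m.predict_proba(features)
        if proba.shape[1] == 1:  # single-class training set
            return np.full(len(features), float(self._m.classes_[0]))
        return proba[:, list(self._m.classes_).index(1)]

    def training_prob(self) -> np.ndarray:
        """Out-of-bag probabilities for the rows the forest was fitted on.

        In-bag probabilities on training rows are overfit (≈ the labels);
        the out-of-bag ones estimate true generalization, which is what the
        calving threshold must reflect.
        """
        oob = self._m.oob_decision_function_
        col = list(self._m.classes_).index(1) if oob.shape[1] > 1 else 0
        p = oob[:, col]
        return np.nan_to_num(p, nan=0.5)  # rows never left out-of-bag


@dataclass
class TrainedDetector:
    """Training data plus a fitted classifier and its calving threshold.

    ``retrain(seed)`` redoes the balanced down-sampling and classifier fit
    with fresh seeds, as the 100-repeat detection protocol requires.  The
    scalar ``threshold`` — the mean probability assigned to fixes inside
    observed calving events by classifiers *not trained on those events*
    (leave-one-event-out) — is fixed at training time and shared by every
    individual; naive in-sample probabilities on event fixes are overfit
    toward 1 and would make detection unattainable.
    """

    features: np.ndarray
    labels: np.ndarray
    event_of_row: np.ndarray  # training-event index per row
    config: DetectorConfig
    classifier_factory: object = None
    classifier: object = None
    threshold: float = field(default=np.nan)

    def _factory(self):
        return self.classifier_factory or (
            lambda s: RandomForestClassifierAdapter(self.config.n_trees, s)
        )

    def _fit_balanced(self, rows: np.ndarray, rng):
        """Balanced down-sampling (without replacement) + classifier fit on
        a subset of training rows."""
        labels = self.labels[rows]
        pos = rows[labels == 1]
        neg = rows[labels == 0]
        if len(pos) == 0:
            raise ValueError("no fixes inside observed calving events")
        if len(neg) == 0:
            raise ValueError("training set has a single class after down-sampling")
        k = min(len(pos), len(neg))
        idx = np.concatenate(
            [rng.choice(pos, size=k, replace=False), rng.choice(neg, size=k, replace=False)]
        )
        clf = self._factory()(int(rng.integers(2**31)))
        clf.fit(self.features[idx], self.labels[idx])
        return clf

    def retrain(self, seed: int):
        rng = np.random.default_rng(seed)
        clf = self._fit_balanced(np.arange(len(self.labels)), rng)
        return clf, self.threshold

    def loeo_threshold(self, seed: int) -> float:
        """Mean held-out probability of in-event fixes, leave-one-event-out."""
        rng = np.random.default_rng(seed)
        events = np.unique(self.event_of_row)
        if len(events) < 2:
            # cannot hold an event out; fall back to in-sample probabilities
            clf = self._fit_balanced(np.arange(len(self.labels)), rng)
            return float(clf.predict_prob(self.features[self.labels == 1]).mean())
        probs = []
        for e in events:
            held = self.event_of_row == e
            if not (self.labels[held] == 1).any():
                continue
            clf = self._fit_balanced(np.nonzero(~held)[0], rng)
            probs.append(clf.predict_prob(self.features[held & (self.labels == 1)]))
        return float(np.concatenate(probs).mean())


def train_event_classifier(
    training: list[tuple[Track, CalvingEvent]],
    config: DetectorConfig | None = None,
    classifier_factory=None,
) -> TrainedDetector:
    """Assemble per-fix features/labels around observed calving events, fit
    the balanced classifier, and derive the single scalar calving threshold
    used for all individuals."""
    config = config or DetectorConfig()
    if not training:
        raise ValueError("need at least one observed calving event")
    feats, labs, evs = [], [], []
    for e_idx, (track, event) in enumerate(training):
        m = season_mask(track, config)
        if not m.any():
            continue
        sub = Track(track.individual_id, track.t[m], track.x[m], track.y[m])
        feats.append(fix_features(sub, config))
        labs.append(event_labels(sub, event, config))
        evs.append(np.full(m.sum(), e_idx))
    features = np.vstack(feats)
    labels = np.concatenate(labs)
    det = TrainedDetector(features, labels, np.concatenate(evs), config, classifier_factory)
    det.threshold = det.loeo_threshold(config.seed)
    det.classifier, _ = det.retrain(config.seed)
    return det


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _window_bounds(t: np.ndarray, length_days: float):
    """Start indices and exclusive end indices of rolling windows that fit
    entirely inside the track (advance fix-by-fix)."""
    span = np.timedelta64(int(length_days * 86400), "s")
    ends = np.searchsorted(t, t + span, side="right")
    starts = np.nonzero(t + span <= t[-1])[0]
    return starts, ends[starts]


def detect_calving(
    track: Track,
    detector: TrainedDetector,
    config: DetectorConfig | None = None,
    seed: int | None = None,
) -> CalvingPrediction | None:
    """Scan one track for a calving event.

    Per repeat, the classifier is retrained with a fresh seed and the track
    scored; per-fix probabilities are averaged across repeats, and the 5-day
    rolling window (advancing fix-by-fix, ties broken by the earliest start)
    with the highest mean probability is returned — provided it exceeds the
    threshold.  Returns ``None`` if no window ever exceeds the threshold.
    """
    config = config or detector.config
    seed = config.seed if seed is None else seed
    m = season_mask(track, config)
    sub = Track(track.individual_id, track.t[m], track.x[m], track.y[m])
    if len(sub) < 3:
        raise ValueError("track has too few in-season fixes")
    starts, ends = _window_bounds(sub.t, config.event_length)
    if len(starts) == 0:
        raise ValueError("track is shorter than one rolling window")
    feats = fix_features(sub, config)

    rng = np.random.default_rng(seed)
    prob_sum = np.zeros(len(sub))
    thresholds = np.empty(config.n_repeats)
    best_dates: list[np.datetime64] = []
    for r in range(config.n_repeats):
        clf, thr = detector.retrain(int(rng.integers(2**31)))
        probs = clf.predict_prob(feats)
        prob_sum += probs
        thresholds[r] = thr
        cs = np.concatenate([[0.0], np.cumsum(probs)])
        wmean = (cs[ends] - cs[starts]) / (ends - starts)
        over = wmean >= thr
        if over.any():
            j = int(np.argmax(np.where(over, wmean, -np.inf)))
            best_dates.append(sub.t[starts[j]].astype("datetime64[D]"))

    avg = prob_sum / config.n_repeats
    threshold = float(thresholds.mean())
    cs = np.concatenate([[0.0], np.cumsum(avg)])
    wmean = (cs[ends] - cs[starts]) / (ends - starts)
    if not (wmean >= threshold).any():
        return None
    j = int(np.argmax(np.where(wmean >= threshold, wmean, -np.inf)))
    t0 = sub.t[starts[j]]
    span_days = (
        0.0
        if not best_dates
        else float((max(best_dates) - min(best_dates)) / np.timedelta64(1, "D"))
    )
    firsts = np.array(best_dates).astype("datetime64[D]").astype(float)
    se = float(firsts.std(ddof=1) / np.sqrt(len(firsts))) if len(firsts) > 1 else 0.0
    start_date = t0.astype("datetime64[D]").astype("O")
    end_date = (t0 + np.timedelta64(int(config.event_length * 86400), "s")).astype(
        "datetime64[D]"
    ).astype("O")
    return CalvingPrediction(
        individual_id=track.individual_id,
        window_start=start_date,
        window_end=end_date,
        mean_prob=float(wmean[j]),
        date_range_days=span_days,
        date_se_days=se,
    )


def screen_tracks(
    tracks: list[Track],
    detector: TrainedDetector,
    config: DetectorConfig | None = None,
    seed: int | None = None,
) -> dict[str, CalvingPrediction | None]:
    """Run detection over candidate tracks; None where no window exceeds
    the threshold.

    The repeat loop retrains the classifier once per repeat and scores every
    track with it (the repeats exist to average over classifier/down-sampling
    randomness, which is shared across tracks), so screening many tracks
    costs little more than screening one.
    """
    config = config or detector.config
    seed = config.seed if seed is None else seed
    subs, feats, bounds = [], [], []
    for tr in tracks:
        m = season_mask(tr, config)
        sub = Track(tr.individual_id, tr.t[m], tr.x[m], tr.y[m])
        if len(sub) < 3:
            raise ValueError(f"track {tr.individual_id} has too few in-season fixes")
        starts, ends = _window_bounds(sub.t, config.event_length)
        if len(starts) == 0:
            raise ValueError(f"track {tr.individual_id} is shorter than one window")
        subs.append(sub)
        feats.append(fix_features(sub, config))
        bounds.append((starts, ends))

    rng = np.random.default_rng(seed)
    prob_sums = [np.zeros(len(s)) for s in subs]
    best_dates: list[list[np.datetime64]] = [[] for _ in subs]
    threshold = detector.threshold
    for _ in range(config.n_repeats):
        clf, _ = detector.retrain(int(rng.integers(2**31)))
        for i, f in enumerate(feats):
            probs = clf.predict_prob(f)
            prob_sums[i] += probs
            starts, ends = bounds[i]
            cs = np.concatenate([[0.0], np.cumsum(probs)])
            wmean = (cs[ends] - cs[starts]) / (ends - starts)
            over = wmean >= threshold
            if over.any():
                j = int(np.argmax(np.where(over, wmean, -np.inf)))
                best_dates[i].append(subs[i].t[starts[j]].astype("datetime64[D]"))

    out: dict[str, CalvingPrediction | None] = {}
    for i, sub in enumerate(subs):
        avg = prob_sums[i] / config.n_repeats
        starts, ends = bounds[i]
        cs = np.concatenate([[0.0], np.cumsum(avg)])
        wmean = (cs[ends] - cs[starts]) / (ends - starts)
        if not (wmean >= threshold).any():
            out[sub.individual_id] = None
            continue
        j = int(np.argmax(np.where(wmean >= threshold, wmean, -np.inf)))
        t0 = sub.t[starts[j]]
        bd = best_dates[i]
        span = float((max(bd) - min(bd)) / np.timedelta64(1, "D")) if bd else 0.0
        firsts = np.array(bd).astype("datetime64[D]").astype(float)
        se = float(firsts.std(ddof=1) / np.sqrt(len(firsts))) if len(firsts) > 1 else 0.0
        out[sub.individual_id] = CalvingPrediction(
            individual_id=sub.individual_id,
            window_start=t0.astype("datetime64[D]").astype("O"),
            window_end=(t0 + np.timedelta64(int(config.event_length * 86400), "s"))
            .astype("datetime64[D]").astype("O"),
            mean_prob=float(wmean[j]),
            date_range_days=span,
            date_se_days=se,
        )
    return out
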