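"""Time-resolved single-feature classification of perceptual direction.

At each time point the momentary value of one signal (smoothed button press
or slow-phase OKN velocity) is used to classify the trial's direction label
(stimulus direction in non-rivalrous trials, dominant-percept label in
rivalrous ones).  Per repetition: classes are balanced by subsampling the
majority class down to ``N = min(NR, NL)``, the balanced set is split 70/30
stratified by class, a maximum-margin threshold classifier is fitted on the
training split and scored on the test split; discriminability is the mean
test accuracy over (by default) 10 such repetitions.  Chance is 50%.

With a single feature a linear maximum-margin classifier reduces to an
oriented threshold; it is implemented directly as the accuracy-maximising
cut placed at the midpoint of the widest margin, which is what a hard-margin
SVM converges to in one dimension (up to tie handling).

Latency of a response curve is the earliest time it reaches halfway between
a baseline and its maximum over the 2-s trial: baseline 0 for speed curves,
0.5 (chance) for discriminability curves.  Button-consistency curves are
also summarised by the fixed 0.5-crossing time, which tracks the
first-consistent-press latency by construction of the smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_REPS",
    "TRAIN_FRACTION",
    "FeatureMatrix",
    "DiscriminabilityCurve",
    "LatencyResult",
    "ThresholdClassifier",
    "balanced_subsample",
    "discriminability_at",
    "discriminability_curve",
    "half_max_latency",
    "consistency_threshold_latency",
]

DEFAULT_REPS = 10
TRAIN_FRACTION = 0.7


@dataclass
class FeatureMatrix:
    """Per-trial feature time courses with direction labels.

    ``values`` is trials x time points; ``labels`` in {-1, +1} per trial;
    ``time_s`` per column, relative to stimulus onset.
    """

    values: np.ndarray
    labels: np.ndarray
    time_s: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.values.shape != (len(self.labels), len(self.time_s)):
            raise ValueError("values must be (n_trials, n_times)")
        if not np.isin(self.labels, (-1, 1)).all():
            raise ValueError("labels must be -1 or +1")


@dataclass
class DiscriminabilityCurve:
    time_s: np.ndarray
    d: np.ndarray  # mean CV accuracy per time point; NaN where undefined
    reps: int = DEFAULT_REPS


@dataclass(frozen=True)
class LatencyResult:
    latency_s: float | None
    half_max: float
    max_value: float


class ThresholdClassifier:
    """Oriented threshold: predict ``orientation`` where value > threshold.

    Fitting scans every candidate cut (midpoints between consecutive
    distinct sorted values, plus the two outer half-planes) for both
    orientations, keeps the accuracy maximisers and, among those, the cut
    with the largest margin to the nearest training point — the 1-D
    equivalent of the maximum-margin separating hyperplane.  Ties between
    equally wide margins resolve to the lowest threshold with orientation
    +1 preferred, making fits deterministic.
    """

    def __init__(self) -> None:
        self.threshold_: float = 0.0
        self.orientation_: int = 1

    def fit(self, x: np.ndarray, y: np.ndarray) -> "ThresholdClassifier":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be matching 1-D arrays")
        classes = np.unique(y)
        if classes.size == 1:
            # degenerate training set: constant prediction via infinite cut
            self.orientation_ = int(classes[0])
            self.threshold_ = -np.inf
            return self
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        uniq = np.unique(xs)
        gap = np.min(np.diff(uniq)) if uniq.size > 1 else 1.0
        cuts = np.concatenate(
            ([uniq[0] - gap], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + gap])
        )
        n = len(xs)
        pos = np.concatenate(([0], np.cumsum(ys == 1)))
        neg = np.concatenate(([0], np.cumsum(ys == -1)))
        ks = np.searchsorted(xs, cuts, "right")  # points at or below each cut
        pos_left, neg_left = pos[ks], neg[ks]
        correct_p = neg_left + (pos[-1] - pos_left)  # orientation +1
        correct_m = pos_left + (neg[-1] - neg_left)  # orientation -1
        margins = np.full(cuts.shape, np.inf)
        interior = (ks > 0) & (ks < n)
        margins[interior] = np.minimum(
            cuts[interior] - xs[ks[interior] - 1], xs[ks[interior]] - cuts[interior]
        )
        corrects = np.concatenate([correct_p, correct_m])
        marg2 = np.concatenate([margins, margins])
        cuts2 = np.concatenate([cuts, cuts])
        orients = np.concatenate([np.ones(cuts.size), -np.ones(cuts.size)])
        # lexicographic max over (accuracy, margin, lowest cut, +1 orientation)
        idx = np.lexsort((orients, -cuts2, marg2, corrects))[-1]
        self.threshold_ = float(cuts2[idx])
        self.orientation_ = int(orients[idx])
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.where(x > self.threshold_, self.orientation_, -self.orientation_)
        return out.astype(int)

    def score(self, x: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(x) == np.asarray(y)))


def balanced_subsample(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a class-balanced subset: all of the minority class plus
    ``N = min(NR, NL)`` drawn without replacement from the majority class."""
    labels = np.asarray(labels, dtype=int)
    n = min(np.count_nonzero(labels == -1), np.count_nonzero(labels == 1))
    if n == 0:
        raise ValueError("both classes must be non-empty")
    # one permutation of all trials, first n of each class: this makes the
    # draw invariant under negating every label (classes swap roles)
    perm = rng.permutation(labels.size)
    keep = [idx for cls in (-1, 1) for idx in perm[labels[perm] == cls][:n]]
    return np.sort(np.asarray(keep))


def _stratified_split(
    labels: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class 70/30 split (train = floor(0.7 * N) per class).

    A single permutation drives both classes so the split, like the
    subsample, is invariant under a global label swap.
    """
    perm = rng.permutation(labels.size)
    train, test = [], []
    for cls in (-1, 1):
        idx = perm[labels[perm] == cls]
        k = int(np.floor(TRAIN_FRACTION * idx.size))
        train.append(idx[:k])
        test.append(idx[k:])
    return np.concatenate(train), np.concatenate(test)


def discriminability_at(
    values_t: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
    reps: int = DEFAULT_REPS,
) -> float:
    """Mean cross-validated accuracy of the threshold classifier on one
    momentary feature, over ``reps`` subsample + 70/30-split repetitions.

    NaN when fewer than 2 trials per class survive balancing (no test set
    can be formed).
    """
    values_t = np.asarray(values_t, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n_per_class = min(np.count_nonzero(labels == -1), np.count_nonzero(labels == 1))
    if n_per_class < 2:
        return float("nan")
    accs = np.empty(reps)
    clf = ThresholdClassifier()
    for r in range(reps):
        sub = balanced_subsample(labels, rng)
        x, y = values_t[sub], labels[sub]
        tr, te = _stratified_split(y, rng)
        clf.fit(x[tr], y[tr])
        accs[r] = clf.score(x[te], y[te])
    return float(np.mean(accs))


def discriminability_curve(
    fm: FeatureMatrix,
    rng: np.random.Generator,
    reps: int = DEFAULT_REPS,
) -> DiscriminabilityCurve:
    """Discriminability at every time point of a feature matrix.

    Columns are processed in time order from the single ``rng`` stream, so
    the whole curve is reproducible bit-for-bit from one seed.
    """
    d = np.array(
        [discriminability_at(fm.values[:, j], fm.labels, rng, reps)
         for j in range(fm.values.shape[1])]
    )
    return DiscriminabilityCurve(time_s=fm.time_s.copy(), d=d, reps=reps)


def half_max_latency(
    time_s: np.ndarray,
    curve: np.ndarray,
    baseline: float = 0.0,
    t_max_search: float = 2.0,
) -> LatencyResult:
    """Earliest time a curve reaches halfway between baseline and its max.

    The maximum is searched over [0, ``t_max_search``] s only (pre-onset
    values sit at baseline by construction).  Undefined when the curve never
    exceeds the baseline.  NaN samples are ignored.
    """
    time_s = np.asarray(time_s, dtype=float)
    curve = np.asarray(curve, dtype=float)
    post = (time_s >= 0.0) & (time_s <= t_max_search) & np.isfinite(curve)
    if not post.any():
        return LatencyResult(None, float("nan"), float("nan"))
    max_value = float(np.max(curve[post]))
    half = baseline + (max_value - baseline) / 2.0
    if max_value <= baseline:
        return LatencyResult(None, half, max_value)
    hit = post & (curve >= half)
    idx = np.flatnonzero(hit)
    return LatencyResult(float(time_s[idx[0]]), half, max_value)


def consistency_threshold_latency(
    time_s: np.ndarray, mean_c: np.ndarray
) -> float | None:
    """Earliest t >= 0 where a mean-consistency curve reaches 0.5."""
    time_s = np.asarray(time_s, dtype=float)
    mean_c = np.asarray(mean_c, dtype=float)
    hit = (time_s >= 0.0) & (mean_c >= 0.5)
    idx = np.flatnonzero(hit)
    return float(time_s[idx[0]]) if idx.size else None
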