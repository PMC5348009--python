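import itertools

import numpy as np
import pytest

from oknbr import discriminability as dd


def brute_force_best_threshold_accuracy(x, y):
    """Exhaustive oracle: best training accuracy of any oriented threshold."""
    x = np.asarray(x, float)
    y = np.asarray(y, int)
    candidates = np.concatenate(([x.min() - 1.0], np.sort(x) + 1e-9, [x.max() + 1.0]))
    best = 0.0
    for c in candidates:
        for orient in (1, -1):
            pred = np.where(x > c, orient, -orient)
            best = max(best, np.mean(pred == y))
    return best


class TestThresholdClassifier:
    def test_perfectly_separable(self):
        x = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        y = np.array([-1, -1, -1, 1, 1, 1])
        clf = dd.ThresholdClassifier().fit(x, y)
        assert clf.score(x, y) == 1.0
        assert clf.threshold_ == pytest.approx(0.0)  # midpoint of widest margin

    def test_inverted_orientation(self):
        x = np.array([-1.0, -2.0, 1.0, 2.0])
        y = np.array([1, 1, -1, -1])
        clf = dd.ThresholdClassifier().fit(x, y)
        assert clf.orientation_ == -1
        assert clf.score(x, y) == 1.0

    def test_matches_brute_force_on_all_labelings(self):
        """Training accuracy equals the exhaustive best threshold for every
        labeling of 8 fixed scalar features."""
        x = np.array([0.1, 0.4, 0.9, 1.5, 2.2, 2.3, 3.7, 4.0])
        for bits in itertools.product([-1, 1], repeat=8):
            y = np.array(bits)
            clf = dd.ThresholdClassifier().fit(x, y)
            assert clf.score(x, y) == pytest.approx(
                brute_force_best_threshold_accuracy(x, y)
            ), f"labeling {bits}"

    def test_monotone_transform_preserves_best_accuracy(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.choice([-1, 1], size=12)
            acc = dd.ThresholdClassifier().fit(x, y).score(x, y)
            for f in (lambda v: 3 * v + 2, np.tanh, lambda v: np.exp(v / 2)):
                acc_t = dd.ThresholdClassifier().fit(f(x), y).score(f(x), y)
                assert acc_t == pytest.approx(acc)

    def test_agrees_with_svm_on_separable_data(self):
        """Independent cross-check: a hard-margin linear SVM on one feature
        picks the same midpoint threshold on separable data."""
        svm = pytest.importorskip("sklearn.svm")
        rng = np.random.default_rng(5)
        for _ in range(10):
            x_neg = rng.uniform(-4, -1, 8)
            x_pos = rng.uniform(1, 4, 8)
            x = np.concatenate([x_neg, x_pos])
            y = np.array([-1] * 8 + [1] * 8)
            clf = dd.ThresholdClassifier().fit(x, y)
            s = svm.SVC(kernel="linear", C=1e6).fit(x[:, None], y)
            # SVC decision boundary: -intercept/w
            boundary = -s.intercept_[0] / s.coef_[0, 0]
            assert clf.threshold_ == pytest.approx(boundary, abs=1e-3)


class TestBalancedSubsample:
    def test_min_rule(self):
        labels = np.array([1] * 8 + [-1] * 5)
        idx = dd.balanced_subsample(labels, np.random.default_rng(0))
        assert len(idx) == 10
        assert np.sum(labels[idx] == 1) == 5
        assert np.sum(labels[idx] == -1) == 5

    def test_equal_classes_keep_everything(self):
        labels = np.array([1] * 7 + [-1] * 7)
        idx = dd.balanced_subsample(labels, np.random.default_rng(0))
        assert len(idx) == 14

    def test_different_rng_states_vary_majority_subset(self):
        labels = np.array([1] * 30 + [-1] * 5)
        draws = {
            tuple(dd.balanced_subsample(labels, np.random.default_rng(s)))
            for s in range(100)
        }
        assert len(draws) > 50  # collisions are rare

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            dd.balanced_subsample(np.ones(5, int), np.random.default_rng(0))


class TestDiscriminabilityAt:
    def test_perfect_separation(self):
        labels = np.array([-1, -1, -1, -1, 1, 1, 1, 1] * 3)
        acc = dd.discriminability_at(labels.astype(float), labels,
                                     np.random.default_rng(0))
        assert acc == 1.0

    def test_chance_for_label_independent_feature(self):
        rng_data = np.random.default_rng(42)
        labels = np.array([1, -1] * 100)
        accs = []
        for seed in range(20):
            values = rng_data.normal(size=200)
            accs.append(
                dd.discriminability_at(values, labels, np.random.default_rng(seed))
            )
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)

    def test_flip_channel_approaches_bayes_rate(self):
        # feature = label with 20% sign flips -> Bayes accuracy 0.8
        rng = np.random.default_rng(7)
        labels = np.array([1, -1] * 200)
        flips = rng.random(400) < 0.2
        values = labels * np.where(flips, -1.0, 1.0) + rng.normal(0, 0.01, 400)
        acc = dd.discriminability_at(values, labels, np.random.default_rng(1))
        assert acc == pytest.approx(0.8, abs=0.05)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=40)
        labels = np.array([1, -1] * 20)
        a = dd.discriminability_at(values, labels, np.random.default_rng(5))
        b = dd.discriminability_at(-values, -labels, np.random.default_rng(5))
        assert a == pytest.approx(b)

    def test_too_few_trials_is_nan(self):
        assert np.isnan(
            dd.discriminability_at(
                np.array([0.0, 1.0, 2.0]), np.array([1, 1, -1]),
                np.random.default_rng(0),
            )
        )

    def test_seeded_reproducibility(self):
        rng_data = np.random.default_rng(2)
        values = rng_data.normal(size=50)
        labels = np.array([1, -1] * 25)
        a = dd.discriminability_at(values, labels, np.random.default_rng(11))
        b = dd.discriminability_at(values, labels, np.random.default_rng(11))
        assert a == b


class TestDiscriminabilityCurve:
    def test_all_columns_separable(self):
        labels = np.array([-1] * 5 + [1] * 5)
        values = np.tile(labels[:, None].astype(float), (1, 7))
        fm = dd.FeatureMatrix(values, labels, np.linspace(0, 2, 7))
        curve = dd.discriminability_curve(fm, np.random.default_rng(0))
        np.testing.assert_allclose(curve.d, 1.0)

    def test_bit_reproducible_with_fixed_seed(self):
        rng_data = np.random.default_rng(1)
        labels = np.array([1, -1] * 10)
        values = rng_data.normal(size=(20, 15))
        fm = dd.FeatureMatrix(values, labels, np.linspace(0, 2, 15))
        c1 = dd.discriminability_curve(fm, np.random.default_rng(3))
        c2 = dd.discriminability_curve(fm, np.random.default_rng(3))
        np.testing.assert_array_equal(c1.d, c2.d)

    def test_onset_latency_shapes_curve(self):
        """Feature driven by the label only after 0.2 s: chance before,
        perfect after."""
        rng = np.random.default_rng(4)
        t = np.linspace(-0.5, 2.0, 26)
        labels = np.array([1, -1] * 15)
        values = np.where(
            t[None, :] < 0.2, rng.normal(size=(30, 26)),
            labels[:, None].astype(float),
        )
        fm = dd.FeatureMatrix(values, labels, t)
        curve = dd.discriminability_curve(fm, np.random.default_rng(0))
        pre = curve.d[t < 0.1]
        post = curve.d[t > 0.3]
        assert np.mean(pre) == pytest.approx(0.5, abs=0.12)
        np.testing.assert_allclose(post, 1.0)


class TestHalfMaxLatency:
    def test_linear_ramp_crosses_at_half(self):
        t = np.linspace(0, 2, 2001)
        curve = np.clip(t, 0, 1)
        res = dd.half_max_latency(t, curve, baseline=0.0)
        assert res.max_value == 1.0
        assert res.latency_s == pytest.approx(0.5, abs=1e-3)

    def test_constant_at_baseline_is_undefined(self):
        t = np.linspace(0, 2, 100)
        res = dd.half_max_latency(t, np.full(100, 0.5), baseline=0.5)
        assert res.latency_s is None

    def test_step_crosses_at_step_time(self):
        t = np.arange(0, 2, 0.01)
        curve = (t >= 0.3).astype(float)
        res = dd.half_max_latency(t, curve, baseline=0.0)
        assert res.latency_s == pytest.approx(0.3, abs=1e-9)

    def test_chance_baseline_yields_075_crossing(self):
        # baseline 0.5, max 1.0: first crossing of 0.75 by hand
        t = np.linspace(0, 2, 201)
        curve = 0.5 + 0.5 * np.clip(t - 0.4, 0, 1)  # reaches 1.0 at t=1.4
        res = dd.half_max_latency(t, curve, baseline=0.5)
        assert res.half_max == pytest.approx(0.75)
        # hand computation: 0.5 + 0.5 (t - 0.4) = 0.75 at t = 0.9
        assert res.latency_s == pytest.approx(0.9, abs=0.011)

    def test_maximum_search_restricted_to_trial(self):
        t = np.linspace(-1, 3, 401)
        curve = np.where(t > 2.5, 10.0, np.clip(t, 0, 1))
        res = dd.half_max_latency(t, curve, baseline=0.0)
        assert res.max_value == 1.0


class TestConsistencyThresholdLatency:
    def test_ramp(self):
        t = np.linspace(0, 2, 201)
        mean_c = np.clip(t, 0, 1)
        assert dd.consistency_threshold_latency(t, mean_c) == pytest.approx(
            0.5, abs=0.011
        )

    def test_never_reaching_half_is_undefined(self):
        t = np.linspace(0, 2, 100)
        assert dd.consistency_threshold_latency(t, np.full(100, 0.4)) is None
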