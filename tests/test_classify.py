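"""Classifier, ROC-sweep, and cross-validation tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinegait import (
    ConfusionCounts,
    HardlimPerceptron,
    PatternMatrix,
    SigmoidMLP,
    ThresholdClassifier,
    confusion,
    cross_validate,
    metrics,
    roc_sweep,
    train_mlp,
    train_perceptron,
    train_rbfn,
)


class TestConfusion:
    def test_perfect_prediction(self):
        truth = np.array([0] * 18 + [1] * 18)
        c = confusion(truth, truth)
        assert (c.tn, c.fp, c.fn, c.tp) == (18, 0, 0, 18)

    def test_complement_prediction(self):
        truth = np.array([0, 0, 1, 1])
        c = confusion(1 - truth, truth)
        assert c.tp == 0 and c.tn == 0 and c.fp == 2 and c.fn == 2

    def test_one_control_misclassified(self):
        # 18 patients all detected, one of 18 controls false-positive
        truth = np.array([0] * 18 + [1] * 18)
        pred = truth.copy()
        pred[0] = 1
        c = confusion(pred, truth)
        assert (c.tn, c.fn, c.fp, c.tp) == (17, 0, 1, 18)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([0, 1], [0, 1, 1])


class TestMetrics:
    def test_published_confusion_rates(self):
        m = metrics(ConfusionCounts(tn=17, fp=1, fn=0, tp=18))
        assert m.accuracy * 100 == pytest.approx(97.2, abs=0.05)
        assert m.sensitivity * 100 == pytest.approx(100.0)
        assert m.specificity * 100 == pytest.approx(94.4, abs=0.05)
        assert m.fpr * 100 == pytest.approx(5.6, abs=0.05)
        assert m.misclassification * 100 == pytest.approx(2.8, abs=0.05)

    def test_half_sensitivity(self):
        m = metrics(ConfusionCounts(tn=5, fp=0, fn=3, tp=3))
        assert m.tpr == pytest.approx(0.5)

    def test_all_correct(self):
        m = metrics(ConfusionCounts(tn=4, fp=0, fn=0, tp=6))
        assert m.accuracy == 1.0

    @given(
        tn=st.integers(0, 50), fp=st.integers(0, 50),
        fn=st.integers(0, 50), tp=st.integers(0, 50),
    )
    @settings(max_examples=60, derandomize=True)
    def test_rate_identities(self, tn, fp, fn, tp):
        if tn + fp == 0 or tp + fn == 0:
            with pytest.raises(ValueError):
                metrics(ConfusionCounts(tn, fp, fn, tp))
            return
        m = metrics(ConfusionCounts(tn, fp, fn, tp))
        assert m.tpr + m.fnr == pytest.approx(1.0)
        assert m.tnr + m.fpr == pytest.approx(1.0)
        assert m.accuracy == pytest.approx(
            (tp + tn) / (tp + tn + fp + fn)
        )


def _brute_force_sweep(values, truth, direction):
    """Exhaustive per-threshold counting oracle (O(n^2))."""
    u = np.unique(values)
    thresholds = [-np.inf, *(0.5 * (u[:-1] + u[1:])), np.inf]
    rows = []
    for t in thresholds:
        pred = values < t if direction == "lower_is_positive" else values > t
        c = confusion(pred, truth)
        rows.append((t, c.tn, c.fp, c.fn, c.tp))
    return rows


class TestRocSweep:
    def test_separated_classes_perfect_accuracy(self):
        values = np.array([0.3, 0.32, 0.35, 0.6, 0.62, 0.7])
        truth = np.array([1, 1, 1, 0, 0, 0])
        sweep = roc_sweep(values, truth, "lower_is_positive")
        assert sweep.optimal_metrics.accuracy == 1.0
        assert 0.35 < sweep.optimal_threshold < 0.6

    @pytest.mark.parametrize("direction", ["lower_is_positive", "higher_is_positive"])
    @pytest.mark.parametrize("q,grid", [(7, 5), (36, 8), (200, 1000), (63, 4)])
    def test_counts_equal_brute_force_oracle(self, q, grid, direction):
        rng = np.random.default_rng(q + grid)
        values = rng.integers(0, grid, q) / grid  # duplicates force ties
        truth = rng.integers(0, 2, q)
        if truth.sum() in (0, q):
            truth[0] = 1 - truth[0]
        sweep = roc_sweep(values, truth, direction)
        oracle = _brute_force_sweep(values, truth, direction)
        assert len(sweep.thresholds) == len(oracle)
        for i, (t, tn, fp, fn, tp) in enumerate(oracle):
            assert sweep.thresholds[i] == t
            assert (sweep.tn[i], sweep.fp[i], sweep.fn[i], sweep.tp[i]) == \
                (tn, fp, fn, tp)

    def test_optimal_maximises_accuracy_with_stated_tie_break(self):
        rng = np.random.default_rng(17)
        values = rng.normal(0, 1, 60)
        truth = (rng.random(60) < 0.5).astype(int)
        truth[0], truth[1] = 1, 0
        sweep = roc_sweep(values, truth, "lower_is_positive")
        best_acc = sweep.accuracy.max()
        assert sweep.optimal_metrics.accuracy == pytest.approx(best_acc)
        # among accuracy-ties, chosen threshold maximises SE+SP then is smallest
        ties = np.flatnonzero(sweep.accuracy == best_acc)
        balance = sweep.tpr[ties] + 1 - sweep.fpr[ties]
        best_balance = balance.max()
        chosen = sweep.thresholds[ties[balance == best_balance]].min()
        assert sweep.optimal_threshold == chosen

    def test_roc_curve_monotone(self):
        rng = np.random.default_rng(23)
        values = rng.normal(0, 1, 100)
        truth = (values + rng.normal(0, 1, 100) < 0).astype(int)
        sweep = roc_sweep(values, truth, "lower_is_positive")
        order = np.argsort(sweep.fpr, kind="stable")
        assert np.all(np.diff(sweep.tpr[order]) >= 0)

    def test_constant_feature_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            sweep = roc_sweep(np.ones(6), [0, 0, 0, 1, 1, 1])
        assert len(sweep.thresholds) == 2

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="per class"):
            roc_sweep([1.0, 2.0], [1, 1])

    def test_gaussian_cohorts_threshold_near_density_crossing(self):
        # large samples from the two stride-length distributions: the
        # accuracy-optimal threshold approaches the equal-density point
        rng = np.random.default_rng(42)
        n = 20000
        values = np.concatenate([
            rng.normal(0.38, 0.07, n), rng.normal(0.54, 0.06, n)
        ])
        truth = np.concatenate([np.ones(n), np.zeros(n)]).astype(int)
        sweep = roc_sweep(values, truth, "lower_is_positive")
        assert 0.44 < sweep.optimal_threshold < 0.48


class TestPatternMatrix:
    def test_one_hot_targets(self):
        pm = PatternMatrix(
            features=np.array([[0.4, 0.5], [0.6, 0.8]]),
            labels=[1, 0],
        )
        np.testing.assert_array_equal(pm.targets, [[0, 1], [1, 0]])
        assert pm.X.shape == (2, 2)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            PatternMatrix(features=np.array([[np.nan, 1.0]]), labels=[0, 1])


def _two_clusters(n=12, gap=3.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([
        rng.normal((0, 0), 0.2, (n, 2)), rng.normal((gap, gap), 0.2, (n, 2))
    ])
    y = np.array([0] * n + [1] * n)
    return X, y


class TestMLP:
    def test_separable_training_accuracy_one(self):
        X, y = _two_clusters()
        model = train_mlp(X, y, seed=0, splits=(1.0, 0, 0), max_epochs=500)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_xor_capacity_majority_of_seeds(self):
        rng = np.random.default_rng(1)
        X = np.vstack([
            rng.normal(c, 0.08, (10, 2))
            for c in [(0, 0), (1, 1), (0, 1), (1, 0)]
        ])
        y = np.array([0] * 20 + [1] * 20)
        good = sum(
            np.mean(
                train_mlp(X, y, seed=s, splits=(1.0, 0, 0),
                          max_epochs=2000, lr=1.0).predict(X) == y
            ) >= 0.9
            for s in range(10)
        )
        assert good > 5

    def test_activations_in_unit_interval(self):
        X, y = _two_clusters(seed=3)
        model = train_mlp(X, y, seed=1)
        A1, A2 = model.activations(X)
        assert A1.shape == (4, len(X)) and A2.shape == (2, len(X))
        for A in (A1, A2):
            assert np.all((A > 0) & (A < 1))

    def test_bit_reproducible_given_seed(self):
        X, y = _two_clusters(seed=5)
        m1 = train_mlp(X, y, seed=9)
        m2 = train_mlp(X, y, seed=9)
        np.testing.assert_array_equal(m1.W1, m2.W1)
        np.testing.assert_array_equal(m1.W2, m2.W2)
        assert not np.array_equal(m1.W1, train_mlp(X, y, seed=10).W1)

    def test_nonfinite_features_error(self):
        X, y = _two_clusters()
        X[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            train_mlp(X, y)

    def test_default_split_fractions(self):
        X, y = _two_clusters(n=30)  # 60 subjects
        model = train_mlp(X, y, seed=0)
        assert len(model.train_idx) == 36
        assert len(model.val_idx) == 12
        assert len(model.test_idx) == 12


class TestRBFN:
    def test_interpolation_regime_perfect_training_accuracy(self):
        X, y = _two_clusters(n=8, seed=2)
        model = train_rbfn(X, y, n_centres=len(X), spread=0.05)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_two_centres_separable(self):
        X, y = _two_clusters(n=10, seed=4)
        model = train_rbfn(X, y, n_centres=2, spread=1.0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_huge_spread_collapses_to_constant(self):
        X, y = _two_clusters(n=10, seed=6)
        model = train_rbfn(X, y, n_centres=4, spread=1e9)
        assert len(np.unique(model.predict(X))) == 1

    def test_duplicate_rows_reduce_centres_with_warning(self):
        X = np.tile(np.array([[0.0, 0.0], [1.0, 1.0]]), (5, 1))
        y = np.array([0, 1] * 5)
        with pytest.warns(UserWarning, match="reducing"):
            model = train_rbfn(X, y, n_centres=6, spread=0.3)
        assert len(model.centres) == 2

    def test_more_centres_than_points_errors(self):
        X, y = _two_clusters(n=3)
        with pytest.raises(ValueError, match="centres"):
            train_rbfn(X, y, n_centres=10)


class TestPerceptron:
    def test_separable_converges_to_perfect(self):
        X, y = _two_clusters(n=10, seed=7)
        model = train_perceptron(X, y, seed=0)
        assert model.converged
        assert np.mean(model.predict(X) == y) == 1.0

    def test_nonseparable_caps_epochs_with_best_so_far(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (40, 2))
        y = rng.integers(0, 2, 40)
        model = train_perceptron(X, y, seed=0, max_epochs=25)
        assert not model.converged
        assert model.n_epochs == 25
        # best-so-far: at least as good as chance on its own training set
        assert np.mean(model.predict(X) == y) >= 0.5

    def test_no_update_on_correct_samples(self):
        X, y = _two_clusters(n=10, seed=7)
        model = train_perceptron(X, y, seed=0)
        again = train_perceptron(X, y, seed=1)  # different order, same sep.
        assert np.mean(again.predict(X) == y) == 1.0


class _ConstantPositive:
    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.ones(len(X), dtype=int)


class TestCrossValidate:
    def test_constant_classifier_balanced_error_half(self):
        X = np.zeros((20, 2))
        y = np.array([0, 1] * 10)
        cv = cross_validate(_ConstantPositive, X, y, k=20)
        assert cv.error_fraction == pytest.approx(0.5)

    def test_separated_threshold_loo_error_zero(self):
        X = np.concatenate([np.linspace(0.3, 0.4, 9), np.linspace(0.6, 0.7, 9)])
        y = np.array([1] * 9 + [0] * 9)
        cv = cross_validate(lambda: ThresholdClassifier(0), X[:, None], y, k=18)
        assert cv.n_misclassified == 0

    def test_loo_equals_manual_enumeration(self):
        rng = np.random.default_rng(12)
        X = rng.normal(0, 1, (10, 1))
        y = (X[:, 0] + rng.normal(0, 0.6, 10) > 0).astype(int)
        if y.sum() in (0, len(y)):
            y[0] = 1 - y[0]
        cv = cross_validate(
            lambda: ThresholdClassifier(0, "higher_is_positive"), X, y, k=10
        )
        manual = 0
        for i in range(10):
            tr = np.ones(10, dtype=bool)
            tr[i] = False
            model = ThresholdClassifier(0, "higher_is_positive").fit(X[tr], y[tr])
            manual += int(model.predict(X[i:i + 1])[0] != y[i])
        assert cv.n_misclassified == manual

    def test_k_greater_than_n_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            cross_validate(_ConstantPositive, np.zeros((4, 1)), [0, 1, 0, 1], k=5)

    def test_stratified_kfold_deterministic_given_seed(self):
        X, y = _two_clusters(n=9, seed=13)
        a = cross_validate(lambda: ThresholdClassifier(0), X, y, k=6, seed=3)
        b = cross_validate(lambda: ThresholdClassifier(0), X, y, k=6, seed=3)
        assert a == b


class TestMLPWrapperIntegration:
    def test_wrapper_roundtrip(self):
        X, y = _two_clusters(n=8, seed=20)
        clf = SigmoidMLP(seed=0, splits=(1.0, 0, 0), max_epochs=300).fit(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_perceptron_wrapper(self):
        X, y = _two_clusters(n=8, seed=21)
        clf = HardlimPerceptron(seed=0).fit(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0
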