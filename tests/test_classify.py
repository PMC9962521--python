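import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from eegsense.classify import (
    ThresholdClassifier,
    TrainedModel,
    f1_from_sen_ppv,
    grid_search_cv,
    impurity,
    linear_decision,
    logistic_prob,
    metrics_from_confusion,
    threshold_predict_combined,
    threshold_train,
    train_model,
)


class TestMetrics:
    def test_published_threshold_row(self):
        """Counts 13/0/15/2 reproduce the threshold classifier's metric row."""
        r = metrics_from_confusion(13, 0, 15, 2).rounded()
        assert r == {"acc": 93.33, "sen": 86.67, "spec": 100.0,
                     "ppv": 100.0, "npv": 88.24, "f1": 92.86}

    def test_perfect_classifier_all_hundred(self):
        r = metrics_from_confusion(10, 0, 10, 0)
        assert all(getattr(r, k) == 100.0
                   for k in ("acc", "sen", "spec", "ppv", "npv", "f1"))

    def test_f1_from_sensitivity_ppv_pairs(self):
        assert round(f1_from_sen_ppv(100.0, 93.33), 2) == 96.55
        assert round(f1_from_sen_ppv(86.67, 100.0), 2) == 92.86

    def test_zero_denominator_flagged(self):
        r = metrics_from_confusion(0, 0, 5, 5)
        assert np.isnan(r.ppv)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_identities_hold_for_random_confusions(self, counts):
        tp, fp, tn, fn = counts
        if tp + fp + tn + fn == 0:
            return
        r = metrics_from_confusion(tp, fp, tn, fn)
        assert r.n == tp + fp + tn + fn
        if tp + fn:
            assert r.sen == pytest.approx(100 * tp / (tp + fn))
        if tn + fp:
            assert r.spec == pytest.approx(100 * tn / (tn + fp))
        if not np.isnan(r.f1):
            assert r.f1 == pytest.approx(
                2 * r.sen * r.ppv / (r.sen + r.ppv)
            )


class TestImpurity:
    def test_balanced_split(self):
        assert impurity([0.5, 0.5], "entropy") == pytest.approx(1.0)
        assert impurity([0.5, 0.5], "gini") == pytest.approx(0.5)

    def test_pure_node_zero(self):
        assert impurity([1.0, 0.0], "entropy") == 0.0
        assert impurity([1.0, 0.0], "gini") == 0.0

    def test_skewed_gini(self):
        assert impurity([0.25, 0.75], "gini") == pytest.approx(0.375)


class TestLinearDecision:
    def test_tie_goes_to_control(self):
        score, label = linear_decision(np.zeros(3), 0.0, np.ones(3))
        assert (score, label) == (0.0, 0)

    def test_arithmetic(self):
        score, label = linear_decision([1.0, -1.0], 0.5, [2.0, 1.0])
        assert score == pytest.approx(1.5) and label == 1

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            linear_decision([1.0], 0.0, [1.0, 2.0])

    def test_sigmoid_at_zero(self):
        assert logistic_prob(np.zeros(2), 0.0, np.ones(2)) == 0.5

    def test_sigmoid_monotone_saturating(self):
        probs = [logistic_prob([1.0], 0.0, [z]) for z in (-10, 0, 10, 100)]
        assert probs == sorted(probs)
        assert probs[-1] == pytest.approx(1.0, abs=1e-9)


class TestNativeAgainstTrainer:
    """Native decision evaluation must reproduce the fitted learner."""

    def _data(self, rng, n=60, p=4):
        X = rng.standard_normal((n, p))
        y = (X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 0.3, n) > 0).astype(int)
        return X, y

    def test_linear_svm_scores_and_labels(self, rng):
        X, y = self._data(rng)
        skl = SVC(kernel="linear", C=1.0).fit(X, y)
        model = train_model(X, y, "svm_linear", C=1.0)
        pts = rng.standard_normal((100, 4))
        assert np.max(np.abs(model.decision_scores(pts)
                             - skl.decision_function(pts))) < 1e-8
        assert np.array_equal(model.predict(pts), skl.predict(pts))

    def test_logistic_probabilities(self, rng):
        X, y = self._data(rng)
        skl = LogisticRegression(solver="liblinear", C=1.0).fit(X, y)
        model = train_model(X, y, "logreg", solver="liblinear", C=1.0)
        pts = rng.standard_normal((100, 4))
        probs = 1 / (1 + np.exp(-model.decision_scores(pts)))
        assert np.max(np.abs(probs - skl.predict_proba(pts)[:, 1])) < 1e-8
        assert np.array_equal(model.predict(pts), skl.predict(pts))

    def test_tree_rules_replay_sklearn(self, rng):
        X, y = self._data(rng)
        skl = DecisionTreeClassifier(criterion="entropy", random_state=0).fit(X, y)
        model = train_model(X, y, "tree", criterion="entropy", seed=0)
        pts = rng.standard_normal((200, 4))
        assert np.array_equal(model.predict(pts), skl.predict(pts))

    def test_model_json_round_trip(self, rng):
        X, y = self._data(rng)
        model = train_model(X, y, "svm_linear", C=0.1)
        back = TrainedModel.from_json(model.to_json())
        pts = rng.standard_normal((50, 4))
        assert np.array_equal(model.predict(pts), back.predict(pts))


class TestThresholdClassifier:
    def test_mean_statistic_threshold(self):
        X = np.array([[4.0], [5.0], [6.0], [1.0], [1.5], [2.0]])
        y = np.array([1, 1, 1, 0, 0, 0])
        model = threshold_train(X, y, statistic="mean")
        assert model.thresholds[0] == pytest.approx(5.0)

    def test_min_statistic_perfect_separation(self):
        X = np.array([[4.0], [5.0], [6.0], [1.0], [2.0], [3.0]])
        y = np.array([1, 1, 1, 0, 0, 0])
        model = threshold_train(X, y, statistic="min")
        assert model.thresholds[0] == 4.0
        assert model.directions[0] == 1
        assert np.array_equal(model.predict(X), y)

    def test_separated_training_data_perfect_accuracy(self, rng):
        # case values sit exactly at their group statistic, controls below
        case = np.full((10, 3), 10.0)
        ctrl = rng.normal(0.0, 0.5, (10, 3))
        X = np.vstack([case, ctrl])
        y = np.array([1] * 10 + [0] * 10)
        model = threshold_train(X, y, statistic="mean")
        assert np.mean(model.predict(X) == y) == 1.0

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError):
            ThresholdClassifier().fit(np.ones((4, 2)), np.ones(4))

    def test_mode_statistic_uses_histogram_midpoint(self):
        vals = np.concatenate([np.full(10, 1.0), np.full(3, 9.0)])
        X = np.column_stack([np.concatenate([vals, np.zeros(5)])])
        y = np.array([1] * 13 + [0] * 5)
        model = threshold_train(X, y, statistic="mode")
        assert model.thresholds[0] < 2.0  # fullest bin is near 1, not 9


class TestGatedThreshold:
    def _gated_setup(self):
        # feature 0: decent but imperfect; feature 1's case-mean rule
        # fires for only some cases and no controls (PPV-pure)
        X = np.array([
            [5.0, 10.0], [6.0, 10.0], [4.0, 0.0], [5.5, 0.0],  # cases
            [3.0, 0.0], [2.0, 0.0], [4.8, 0.0], [1.0, 0.0],    # controls
        ])
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        return X, y

    def test_gate_is_ppv_pure_on_training(self):
        X, y = self._gated_setup()
        clf = ThresholdClassifier(statistic="mean", use_gate=True).fit(X, y)
        assert clf.gate_ is not None
        assert clf.gate_["fire_on"] == 1

    def test_gate_overrides_primary(self):
        X, y = self._gated_setup()
        model = threshold_train(X, y, statistic="mean", use_gate=True)
        row = {model.feature_keys[0]: -100.0, model.feature_keys[1]: 10.0}
        assert threshold_predict_combined(model, row) == 1

    def test_silent_gate_falls_through_to_primary(self):
        X, y = self._gated_setup()
        model = threshold_train(X, y, statistic="mean", use_gate=True)
        row = {model.feature_keys[0]: 100.0, model.feature_keys[1]: 0.0}
        assert threshold_predict_combined(model, row) == 1

    def test_missing_feature_named(self):
        X, y = self._gated_setup()
        model = threshold_train(X, y, statistic="mean", use_gate=True)
        with pytest.raises(KeyError):
            threshold_predict_combined(model, {})

    def test_gating_does_not_hurt_training_accuracy(self):
        X, y = self._gated_setup()
        plain = ThresholdClassifier(statistic="min").fit(X, y)
        gated = ThresholdClassifier(statistic="mean", use_gate=True).fit(X, y)
        assert np.mean(gated.predict(X) == y) >= np.mean(plain.predict(X) == y)


class TestGridSearchCV:
    def test_too_few_subjects_per_class_rejected(self, small_table):
        with pytest.raises(ValueError, match="per class"):
            grid_search_cv(small_table, model_kind="svm_linear", k=10)

    def test_degenerate_grid_matches_direct_evaluation(self, small_table):
        m1, r1 = grid_search_cv(small_table, model_kind="svm_linear",
                                grid=[{"C": 1.0}], k=3, seed=0, rfe_n=None)
        m2, r2 = grid_search_cv(small_table, model_kind="svm_linear",
                                grid=[{"C": 1.0}], k=3, seed=0, rfe_n=None)
        assert r1.rounded() == r2.rounded()
        assert r1.hyperparams == {"C": 1.0}

    def test_shuffled_labels_give_chance_accuracy(self, small_table):
        rng = np.random.default_rng(0)
        y = (small_table.groups == "case").astype(int).to_numpy()
        y_null = rng.permutation(y)
        _, rep = grid_search_cv(small_table, labels=y_null,
                                model_kind="tree", grid=[{"criterion": "gini",
                                                          "splitter": "best"}],
                                k=3, seed=0, rfe_n=None)
        assert 10.0 <= rep.acc <= 90.0

    def test_fold_counts_partition_subjects(self, small_table):
        _, rep = grid_search_cv(small_table, model_kind="threshold",
                                grid=[{"statistic": "mean"}], k=3, seed=0,
                                rfe_n=None)
        assert rep.n == small_table.n_subjects
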