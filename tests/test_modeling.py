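"""Splitting policy, classifier tuning and performance metrics."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

import herbiscreen as hs
from herbiscreen import workflows as wf
from herbiscreen.errors import ValidationError
from herbiscreen.modeling import split_ids_by_class


def _labelled(sizes: dict[str, int]):
    ids, labels = [], []
    for label, n in sizes.items():
        for j in range(n):
            ids.append(f"{label}{j}")
            labels.append(label)
    return ids, labels


class TestStratifiedSplit:
    def test_class_size_policy(self):
        ids, labels = _labelled({"A": 10, "B": 4, "C": 2})
        train, test, excluded = split_ids_by_class(ids, labels, hs.SplitSpec(seed=3))
        in_train = lambda lab: sum(i.startswith(lab) for i in train)
        in_test = lambda lab: sum(i.startswith(lab) for i in test)
        assert (in_train("A"), in_test("A")) == (8, 2)   # 80:20
        assert (in_train("B"), in_test("B")) == (2, 2)   # 50:50 for 3-5 members
        assert set(excluded) == {"C0", "C1"}             # < 3 members excluded

    def test_odd_small_class_rounds_half_up(self):
        ids, labels = _labelled({"A": 5})
        train, test, _ = split_ids_by_class(ids, labels, hs.SplitSpec(seed=0))
        assert (len(train), len(test)) == (3, 2)

    def test_partition_property(self):
        ids, labels = _labelled({"A": 13, "B": 7, "C": 4, "D": 1})
        train, test, excluded = split_ids_by_class(ids, labels, hs.SplitSpec(seed=5))
        assert sorted(train + test + excluded) == sorted(ids)
        assert not (set(train) & set(test))
        assert not (set(train) | set(test)) & set(excluded)

    def test_unlabelled_records_are_excluded(self):
        train, test, excluded = split_ids_by_class(
            ["a", "b", "c", "d"], ["A", "A", "A", None], hs.SplitSpec(seed=1)
        )
        assert "d" in excluded

    def test_deterministic_given_seed(self):
        ids, labels = _labelled({"A": 20, "B": 9})
        first = split_ids_by_class(ids, labels, hs.SplitSpec(seed=42))
        second = split_ids_by_class(ids, labels, hs.SplitSpec(seed=42))
        third = split_ids_by_class(ids, labels, hs.SplitSpec(seed=43))
        assert first == second
        assert first != third

    def test_compound_set_interface(self, moa_set):
        train, test, excluded = hs.stratified_split(
            moa_set, "moa_label", hs.SplitSpec(seed=2)
        )
        assert len(train) + len(test) + len(excluded) == len(moa_set)


class TestConfusionMetrics:
    def test_worked_example(self):
        y_true = ["p"] * 50 + ["n"] * 50
        y_pred = ["p"] * 40 + ["n"] * 10 + ["p"] * 5 + ["n"] * 45
        m = hs.confusion_metrics(y_true, y_pred, "p")
        assert (m.tp, m.fn, m.fp, m.tn) == (40, 10, 5, 45)
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.9)
        assert m.precision == pytest.approx(0.8889, abs=1e-4)
        assert m.accuracy == pytest.approx(0.85)
        assert m.f1 == pytest.approx(0.8421, abs=1e-4)
        assert m.kappa == pytest.approx(0.7)
        assert m.balanced_accuracy == pytest.approx(0.85)

    def test_perfect_prediction(self):
        m = hs.confusion_metrics(["a", "b"] * 5, ["a", "b"] * 5, "a")
        assert m.sensitivity == m.specificity == m.precision == m.f1 == 1.0
        assert m.kappa == 1.0

    def test_constant_predictor_on_balanced_binary_has_zero_kappa(self):
        m = hs.confusion_metrics(["a", "a", "b", "b"], ["a"] * 4, "a")
        assert m.kappa == 0.0

    def test_degenerate_denominator_flagged(self):
        # no true positives in truth: TP+FN = 0, so sensitivity is 0/0
        m = hs.confusion_metrics(["a", "a"], ["b", "b"], "b")
        assert m.sensitivity == 0.0
        assert "sensitivity" in m.degenerate

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValidationError):
            hs.confusion_metrics([], [], "a")


class TestMulticlassReport:
    def test_perfect_three_class(self):
        y = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        rep = hs.multiclass_report(y, y)
        assert rep.overall_accuracy == 1.0
        assert rep.macro["sensitivity"] == 1.0
        assert rep.kappa == 1.0

    def test_systematic_confusion_matches_hand_counts(self):
        y_true = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        y_pred = ["a"] * 4 + ["b", "b", "c", "c"] + ["c"] * 4
        rep = hs.multiclass_report(y_true, y_pred)
        b = rep.per_class["b"]
        assert (b.tp, b.fn, b.fp, b.tn) == (2, 2, 0, 8)
        c = rep.per_class["c"]
        assert (c.tp, c.fn, c.fp, c.tn) == (4, 0, 2, 6)
        assert rep.overall_accuracy == pytest.approx(10 / 12)
        assert rep.kappa == pytest.approx(0.75)
        assert rep.kappa == pytest.approx(cohen_kappa_score(y_true, y_pred))

    def test_macro_average_is_mean_of_per_class(self):
        y_true = ["a"] * 5 + ["b"] * 5
        y_pred = ["a"] * 4 + ["b"] + ["b"] * 3 + ["a"] * 2
        rep = hs.multiclass_report(y_true, y_pred)
        expected = np.mean([rep.per_class["a"].f1, rep.per_class["b"].f1])
        assert rep.macro["f1"] == pytest.approx(expected)

    def test_accuracy_equals_trace_over_n(self, moa_set, moa_bundle):
        bundle, test_ids, _ = moa_bundle
        X = wf.moa_features_for(moa_set.subset(test_ids), bundle)
        y_true = np.asarray(moa_set.subset(test_ids).labels("moa_label"))
        y_pred = bundle.predict_with_probabilities(X.to_numpy())[2]
        rep = hs.multiclass_report(y_true, y_pred)
        assert rep.overall_accuracy == pytest.approx(np.mean(y_true == y_pred))


class TestTuneAndTrain:
    def test_separable_scaffold_classes_reach_high_cv_accuracy(self, moa_bundle):
        bundle, _, _ = moa_bundle
        assert bundle.estimator.cv_accuracy_ >= 0.95

    def test_same_seed_selects_same_hyperparameters(self, moa_set):
        features, retained = wf.build_fingerprint_features(moa_set)
        y = moa_set.labels("moa_label")
        kwargs = dict(cv={"folds": 3, "repeats": 1}, seed=7, n_trees=60)
        a = hs.tune_and_train(features.to_numpy(), y, **kwargs)
        b = hs.tune_and_train(features.to_numpy(), y, **kwargs)
        assert a.estimator.best_params_ == b.estimator.best_params_
        assert a.estimator.cv_accuracy_ == b.estimator.cv_accuracy_

    def test_grid_of_size_one(self, moa_set):
        features, _ = wf.build_fingerprint_features(moa_set)
        bundle = hs.tune_and_train(
            features.to_numpy(), moa_set.labels("moa_label"),
            grid=[{"max_features": 3}], cv={"folds": 3, "repeats": 1},
            seed=0, n_trees=60,
        )
        assert bundle.estimator.best_params_ == {"max_features": 3}
        assert len(bundle.estimator.resample_scores_[0]) == 3

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            hs.HerbicideClassifier().fit(np.zeros((4, 2)), ["a"] * 4)

    def test_probabilities_sum_to_one_and_ties_break_by_vocabulary(self, moa_set, moa_bundle):
        bundle, test_ids, _ = moa_bundle
        X = wf.moa_features_for(moa_set.subset(test_ids), bundle)
        probs, max_p, labels = hs.class_probabilities(bundle, X.to_numpy())
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(max_p == probs.max(axis=1))
        assert set(labels) <= set(bundle.classes)

    def test_training_compounds_predicted_confidently(self, moa_bundle):
        # a well-fit model assigns its own training compounds their labels
        # with class probability above 0.6
        bundle, _, _ = moa_bundle
        probs, max_p, labels = bundle.predict_with_probabilities(
            bundle.training_features
        )
        assert np.all(max_p > 0.6)

    def test_feature_mismatch_rejected(self, moa_bundle):
        bundle, _, _ = moa_bundle
        with pytest.raises(ValidationError):
            bundle.estimator.predict(np.zeros((2, 3)))

    @pytest.mark.parametrize("algorithm", ["svm", "nb", "xgboost"])
    def test_alternative_classifiers_pluggable(self, moa_set, algorithm):
        features, _ = wf.build_fingerprint_features(moa_set)
        bundle = hs.tune_and_train(
            features.to_numpy(), moa_set.labels("moa_label"),
            algorithm=algorithm, cv={"folds": 3, "repeats": 1}, seed=1,
        )
        probs = bundle.estimator.predict_proba(features.to_numpy()[:5])
        assert probs.shape == (5, 4)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
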