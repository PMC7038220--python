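"""PNN behaviour, classifier wiring, confusion metrics and cross-validation."""

import numpy as np
import pytest

from bispeeg import (
    ClassifierSpec,
    PNNClassifier,
    accuracy_vs_n_features,
    confusion_metrics,
    cross_validate,
    make_classifier,
    pnn_fit,
    pnn_predict,
)


class TestPNN:
    def test_small_sigma_degenerates_to_nearest_neighbour(self, rng):
        X = rng.standard_normal((40, 3))
        y = rng.choice(["a", "b"], size=40)
        while len(set(y)) < 2:
            y = rng.choice(["a", "b"], size=40)
        Xt = rng.standard_normal((25, 3))
        scale = X.std()
        pnn = pnn_fit(X, y, sigma=1e-6 * scale)
        d2 = ((Xt[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
        nn_labels = y[np.argmin(d2, axis=1)]
        np.testing.assert_array_equal(pnn.predict(Xt), nn_labels)

    def test_large_sigma_degenerates_to_majority_vote(self, rng):
        X = rng.standard_normal((30, 2))
        y = np.array(["maj"] * 19 + ["min"] * 11)
        pnn = pnn_fit(X, y, sigma=1e6 * X.std())
        pred = pnn.predict(rng.standard_normal((20, 2)))
        assert np.all(pred == "maj")

    def test_closed_form_score_ratio(self):
        """Two point-classes at -1 and +1, sigma=0.1: x=0.9 is decisively +1."""
        X = np.array([[-1.0], [1.0]])
        y = np.array(["neg", "pos"])
        state = pnn_fit(X, y, sigma=0.1)
        pred, scores = pnn_predict(state, np.array([[0.9]]))
        assert pred[0] == "pos"
        expected = np.exp(-0.1**2 / 0.02) / np.exp(-1.9**2 / 0.02)
        assert scores[0, 1] / scores[0, 0] == pytest.approx(expected, rel=1e-9)
        assert scores[0, 1] / scores[0, 0] > 10

    def test_tie_goes_to_first_seen_class(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array(["first", "second"])
        pnn = pnn_fit(X, y, sigma=1.0)
        assert pnn.predict(np.array([[0.0]]))[0] == "first"

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            pnn_fit(np.zeros((3, 1)), np.array(["a", "a", "a"]), sigma=1.0)

    def test_sigma_grid_search_is_deterministic(self, rng):
        X = np.vstack([rng.normal(-1, 0.3, (15, 2)), rng.normal(1, 0.3, (15, 2))])
        y = np.array(["a"] * 15 + ["b"] * 15)
        s1 = PNNClassifier().fit(X, y).sigma_
        s2 = PNNClassifier().fit(X, y).sigma_
        assert s1 == s2 > 0


class TestMakeClassifier:
    def _fit_predict_train(self, kind, X, y):
        clf = make_classifier(ClassifierSpec(kind=kind))
        clf.fit(X, y)
        return np.mean(clf.predict(X) == y)

    def test_linear_model_separates_linear_toy(self, rng):
        X = np.vstack([rng.normal(-2, 0.2, (20, 2)), rng.normal(2, 0.2, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        assert self._fit_predict_train("svm_poly1", X, y) == 1.0

    def test_xor_needs_nonlinear_kernel(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        X = np.repeat(X, 5, axis=0)
        y = np.repeat([0, 1, 1, 0], 5)
        assert self._fit_predict_train("svm_poly1", X, y) <= 0.75
        assert self._fit_predict_train("svm_rbf", X, y) == 1.0

    def test_1nn_memorises_training_set(self, rng):
        X = rng.standard_normal((30, 4))
        y = rng.choice([0, 1], size=30)
        clf = make_classifier(ClassifierSpec(kind="knn", knn_k=1))
        clf.fit(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown classifier"):
            ClassifierSpec(kind="random_forest")


class TestConfusionMetrics:
    def test_near_perfect_row(self):
        m = confusion_metrics(TP=40, FN=0, TN=36, FP=1)
        assert round(m["accuracy"], 2) == 98.70
        assert round(m["sensitivity"], 2) == 100.00
        assert round(m["specificity"], 2) == 97.30
        assert round(m["ppv"], 2) == 97.56

    def test_two_error_row(self):
        m = confusion_metrics(TP=39, FN=1, TN=36, FP=1)
        assert round(m["accuracy"], 2) == 97.40
        assert round(m["sensitivity"], 2) == 97.50
        assert round(m["specificity"], 2) == 97.30
        assert round(m["ppv"], 2) == 97.50

    def test_undefined_ratios_are_nan_not_zero(self):
        m = confusion_metrics(TP=0, FN=0, TN=10, FP=0)
        assert np.isnan(m["sensitivity"]) and np.isnan(m["ppv"])
        assert m["specificity"] == 100.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(0, 0, 0, 0)


class TestCrossValidate:
    def _cohort(self, rng, informative=False):
        n_pos, n_neg = 40, 37
        X = rng.standard_normal((n_pos + n_neg, 4))
        y = np.array(["asd"] * n_pos + ["normal"] * n_neg)
        if informative:
            X[:n_pos, 0] += 6.0
        return X, y

    def test_majority_baseline_accuracy(self, rng):
        """sigma -> inf PNN always votes the training majority (ASD, 40 of 77)."""
        X, y = self._cohort(rng)
        res = cross_validate(X, y, ClassifierSpec(kind="pnn", pnn_sigma=1e9),
                             n_folds=10, seed=3)
        assert res.accuracy == pytest.approx(100 * 40 / 77, abs=1e-9)
        assert res.TP == 40 and res.FN == 0 and res.TN == 0 and res.FP == 37

    def test_null_features_near_chance(self, rng):
        """Uninformative features stay inside the binomial band around 51.95%."""
        accs = [
            cross_validate(*self._cohort(rng), ClassifierSpec(kind="knn"),
                           n_folds=10, seed=s).accuracy
            for s in range(8)
        ]
        assert 30.0 < np.mean(accs) < 70.0

    def test_informative_features_separate(self, rng):
        X, y = self._cohort(rng, informative=True)
        res = cross_validate(X, y, ClassifierSpec(kind="pnn"), n_folds=10, seed=3)
        assert res.accuracy > 95.0

    def test_counts_partition_cohort(self, rng):
        X, y = self._cohort(rng)
        res = cross_validate(X, y, ClassifierSpec(kind="lda"), n_folds=10, seed=1)
        assert res.TP + res.FN == 40
        assert res.TN + res.FP == 37
        assert len(res.fold_counts) == 10

    def test_seed_determinism(self, rng):
        X, y = self._cohort(rng, informative=True)
        r1 = cross_validate(X, y, ClassifierSpec(kind="lda"), seed=5)
        r2 = cross_validate(X, y, ClassifierSpec(kind="lda"), seed=5)
        assert r1.fold_counts == r2.fold_counts

    def test_too_many_folds_rejected(self, rng):
        X, y = self._cohort(rng)
        with pytest.raises(ValueError, match="n_folds"):
            cross_validate(X, y, n_folds=50)


class TestAccuracyCurve:
    def test_curve_shape_and_tie_rule(self, rng):
        X = rng.standard_normal((60, 3))
        y = np.array(["a"] * 30 + ["b"] * 30)
        X[:30, 0] += 8.0  # perfect feature first in the ranking
        curve, best = accuracy_vs_n_features(X, y, [0, 1, 2],
                                             ClassifierSpec(kind="lda"),
                                             n_folds=5, seed=2)
        assert len(curve) == 3
        assert curve[0][1] == 100.0
        assert best == 1  # smallest m among ties at 100%

    def test_noise_feature_cannot_help(self, rng):
        X = rng.standard_normal((60, 2))
        y = np.array(["a"] * 30 + ["b"] * 30)
        X[:30, 0] += 10.0
        curve, _ = accuracy_vs_n_features(X, y, [0, 1], ClassifierSpec(kind="pnn", pnn_sigma=0.5),
                                          n_folds=5, seed=4)
        one_sample = 100.0 / 60.0
        assert curve[1][1] <= curve[0][1] + one_sample + 1e-9

    def test_empty_ranking_rejected(self, rng):
        with pytest.raises(ValueError):
            accuracy_vs_n_features(rng.standard_normal((10, 2)),
                                   np.array(["a"] * 5 + ["b"] * 5), [])
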