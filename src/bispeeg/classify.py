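"""Classifiers and cross-validated evaluation for the two-class EEG task.

The probabilistic neural network (PNN) — a Parzen-window kernel density
classifier — is implemented here; the standard baselines (LDA, QDA, KNN,
SVM with RBF and polynomial kernels of degree 1-3) are delegated to
scikit-learn behind one uniform spec.  Evaluation is stratified 10-fold
cross-validation with confusion counts pooled over held-out folds
(micro-average); accuracy, sensitivity, specificity and PPV are reported in
percent with ASD as the positive class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

log = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "CVResult",
    "PNNClassifier",
    "pnn_fit",
    "pnn_predict",
    "make_classifier",
    "confusion_metrics",
    "cross_validate",
    "accuracy_vs_n_features",
]

CLASSIFIER_KINDS = (
    "pnn", "lda", "qda", "knn",
    "svm_poly1", "svm_poly2", "svm_poly3", "svm_rbf",
)


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to build and its hyperparameters.

    ``pnn_sigma=None`` selects the Parzen width by inner-fold grid search
    over a log-spaced range 0.01..10 (on standardized features).
    """

    kind: str = "pnn"
    pnn_sigma: float | None = None
    knn_k: int = 5
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; choose from {CLASSIFIER_KINDS}")
        if self.pnn_sigma is not None and self.pnn_sigma <= 0:
            raise ValueError("pnn_sigma must be positive")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


class PNNClassifier(BaseEstimator, ClassifierMixin):
    """Probabilistic neural network: Gaussian Parzen-window density per class.

    The pattern layer holds every training point; the summation layer forms

        g_c(x) = (n_c / N) * (1 / n_c) sum_{i in c} exp(-||x - x_i||^2 / (2 sigma^2))

    i.e. the class-conditional Parzen density times the empirical class
    prior, and the output layer predicts the argmax.  With the prior factor
    the classifier degenerates to 1-nearest-neighbour as sigma -> 0 and to
    the training majority class as sigma -> inf.  Ties go to the class seen
    first in the training labels.

    ``sigma=None`` triggers a deterministic inner stratified-CV grid search
    over ``sigma_grid``.
    """

    def __init__(self, sigma: float | None = None,
                 sigma_grid: np.ndarray | None = None,
                 inner_folds: int = 3, random_state: int = 0):
        self.sigma = sigma
        self.sigma_grid = sigma_grid
        self.inner_folds = inner_folds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        # classes in order of first appearance: the documented tie-break order
        self.classes_ = np.array(list(dict.fromkeys(y.tolist())))
        if len(self.classes_) < 2:
            raise ValueError("PNN needs training samples from at least two classes")
        for c in self.classes_:
            if not np.any(y == c):
                raise ValueError(f"empty class {c!r}")
        self.X_ = X
        self.y_ = y
        if self.sigma is not None:
            self.sigma_ = float(self.sigma)
        else:
            self.sigma_ = self._grid_search_sigma(X, y)
        return self

    def _grid_search_sigma(self, X, y) -> float:
        grid = self.sigma_grid
        if grid is None:
            grid = np.logspace(-2, 1, 16)
        n_min = min(np.sum(y == c) for c in self.classes_)
        folds = max(2, min(self.inner_folds, int(n_min)))
        if n_min < 2:  # cannot cross-validate; median heuristic on the grid
            return float(np.median(grid))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=self.random_state)
        best_sigma, best_acc = float(grid[0]), -1.0
        for sigma in grid:
            correct = 0
            for tr, te in skf.split(X, y):
                sub = PNNClassifier(sigma=float(sigma)).fit(X[tr], y[tr])
                correct += int(np.sum(sub.predict(X[te]) == y[te]))
            acc = correct / len(y)
            if acc > best_acc:  # strict: ties keep the smaller sigma
                best_acc, best_sigma = acc, float(sigma)
        return best_sigma

    def decision_scores(self, X) -> np.ndarray:
        """Scores proportional to the prior-weighted Parzen class densities.

        One column per class in training order.  Each row is rescaled by a
        positive constant (the kernel at the nearest training point) so that
        tiny sigmas cannot underflow every kernel at once; argmax, ratios
        and normalised probabilities are unaffected.
        """
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.X_[None, :, :]) ** 2).sum(axis=2)
        d2 = d2 - d2.min(axis=1, keepdims=True)
        kernels = np.exp(-d2 / (2.0 * self.sigma_**2))
        N = len(self.y_)
        return np.stack(
            [kernels[:, self.y_ == c].sum(axis=1) / N for c in self.classes_],
            axis=1,
        )

    def predict(self, X):
        scores = self.decision_scores(X)
        # argmax returns the first maximum: ties go to the first-seen class
        return self.classes_[np.argmax(scores, axis=1)]

    def predict_proba(self, X):
        s = self.decision_scores(X)
        total = s.sum(axis=1, keepdims=True)
        total[total == 0.0] = 1.0
        return s / total


def pnn_fit(X, y, sigma: float | None = None) -> PNNClassifier:
    """Functional wrapper: fit a PNN and return its state."""
    return PNNClassifier(sigma=sigma).fit(X, y)


def pnn_predict(state: PNNClassifier, X) -> tuple[np.ndarray, np.ndarray]:
    """Predicted classes and per-class scores for new points."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return state.predict(X), state.decision_scores(X)


def make_classifier(spec: ClassifierSpec):
    """Build a fit/predict estimator from a spec.

    Distance- and kernel-based models (PNN, KNN, SVM) are wrapped with a
    standard scaler fitted on the training fold, so that fixed
    hyperparameter ranges (e.g. the PNN sigma grid) refer to unit-variance
    features; LDA/QDA are scale-equivariant and used as-is.
    """
    kind = spec.kind
    if kind == "lda":
        return LinearDiscriminantAnalysis()
    if kind == "qda":
        return QuadraticDiscriminantAnalysis()
    if kind == "knn":
        clf = KNeighborsClassifier(n_neighbors=spec.knn_k)
    elif kind == "pnn":
        clf = PNNClassifier(sigma=spec.pnn_sigma)
    elif kind == "svm_rbf":
        clf = SVC(kernel="rbf", C=spec.svm_c, gamma=spec.svm_gamma)
    elif kind.startswith("svm_poly"):
        degree = int(kind[-1])
        clf = SVC(kernel="poly", degree=degree, C=spec.svm_c, gamma="auto", coef0=1.0)
    else:  # pragma: no cover - spec validation makes this unreachable
        raise ValueError(f"unknown classifier kind {kind!r}")
    if spec.standardize:
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    return clf


def confusion_metrics(TP: int, FN: int, TN: int, FP: int) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and PPV in percent from counts.

    Computed in exact rational arithmetic before conversion to float.
    A zero-denominator ratio is reported as NaN, never as 0.
    """
    counts = (TP, FN, TN, FP)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be >= 0")
    if sum(counts) == 0:
        raise ValueError("confusion counts are all zero")

    def pct(num: int, den: int) -> float:
        return float(100 * Fraction(num, den)) if den > 0 else float("nan")

    return {
        "accuracy": pct(TP + TN, TP + TN + FP + FN),
        "sensitivity": pct(TP, TP + FN),
        "specificity": pct(TN, TN + FP),
        "ppv": pct(TP, TP + FP),
    }


@dataclass
class CVResult:
    """Pooled and per-fold confusion counts of one cross-validation run."""

    TP: int
    FN: int
    TN: int
    FP: int
    fold_counts: list[tuple[int, int, int, int]]
    n_folds: int
    seed: int
    positive_label: str
    n_features_used: int

    @property
    def metrics(self) -> dict[str, float]:
        return confusion_metrics(self.TP, self.FN, self.TN, self.FP)

    @property
    def accuracy(self) -> float:
        return self.metrics["accuracy"]


def _pick_positive(y: np.ndarray, positive_label) -> object:
    if positive_label is not None:
        return positive_label
    uniq = set(np.unique(y).tolist())
    for cand in ("asd", "ASD", 1, "1", True):
        if cand in uniq:
            return cand
    return sorted(uniq, key=str)[-1]


def cross_validate(
    X,
    y,
    spec: ClassifierSpec | None = None,
    n_folds: int = 10,
    seed: int = 0,
    group_ids=None,
    positive_label=None,
    reducer_factory=None,
) -> CVResult:
    """Stratified k-fold evaluation with pooled confusion counts.

    ``reducer_factory``, when given, returns a fresh object with
    ``fit(X, y) -> self`` and ``transform(X)`` per fold; it is fitted on the
    training fold only, so supervised reductions run leakage-free.
    Group-aware stratification is used when ``group_ids`` is supplied.
    If some training fold lacks a class, the split is re-seeded (logged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    spec = spec or ClassifierSpec()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("binary task expected")
    if group_ids is None and n_folds > counts.min():
        raise ValueError(
            f"n_folds={n_folds} exceeds the minority class count {counts.min()}"
        )
    pos = _pick_positive(y, positive_label)

    for attempt in range(5):
        split_seed = seed + attempt
        if group_ids is None:
            splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=split_seed)
            splits = list(splitter.split(X, y))
        else:
            splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True,
                                            random_state=split_seed)
            splits = list(splitter.split(X, y, groups=np.asarray(group_ids)))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in splits):
            break
        log.warning("fold with single-class training set at seed %d; re-seeding", split_seed)
    else:
        raise RuntimeError("could not build folds with both classes in every training set")

    fold_counts = []
    TP = FN = TN = FP = 0
    n_features_used = X.shape[1]
    for tr, te in splits:
        Xtr, Xte = X[tr], X[te]
        if reducer_factory is not None:
            reducer = reducer_factory().fit(Xtr, y[tr])
            Xtr, Xte = reducer.transform(Xtr), reducer.transform(Xte)
            n_features_used = Xtr.shape[1]
        model = make_classifier(spec)
        model.fit(Xtr, y[tr])
        pred = np.asarray(model.predict(Xte))
        is_pos = y[te] == pos
        tp = int(np.sum((pred == pos) & is_pos))
        fn = int(np.sum((pred != pos) & is_pos))
        tn = int(np.sum((pred != pos) & ~is_pos))
        fp = int(np.sum((pred == pos) & ~is_pos))
        fold_counts.append((tp, fn, tn, fp))
        TP, FN, TN, FP = TP + tp, FN + fn, TN + tn, FP + fp

    return CVResult(TP=TP, FN=FN, TN=TN, FP=FP, fold_counts=fold_counts,
                    n_folds=n_folds, seed=seed, positive_label=str(pos),
                    n_features_used=n_features_used)


def accuracy_vs_n_features(
    X,
    y,
    ranked_indices,
    spec: ClassifierSpec | None = None,
    n_folds: int = 10,
    seed: int = 0,
    group_ids=None,
    positive_label=None,
) -> tuple[list[tuple[int, float]], int]:
    """CV accuracy using the top-m ranked features, for m = 1..len(ranking).

    Returns the (m, accuracy) curve and the argmax m (smallest m on ties).
    """
    ranked = [int(j) for j in ranked_indices]
    if not ranked:
        raise ValueError("empty feature ranking")
    X = np.asarray(X, dtype=float)
    curve = []
    for m in range(1, len(ranked) + 1):
        res = cross_validate(X[:, ranked[:m]], y, spec, n_folds=n_folds, seed=seed,
                             group_ids=group_ids, positive_label=positive_label)
        curve.append((m, res.accuracy))
    best_m = max(curve, key=lambda t: (t[1], -t[0]))[0]
    return curve, best_m
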