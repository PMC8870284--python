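"""Cross-validated classification of the two cohorts.

Three classifiers distinguish middle-aged-like from elderly-like feature
vectors under stratified 10-fold cross-validation: K-nearest neighbors
(Euclidean, K in {1, 3, 5}), a support vector machine with the Pearson VII
universal kernel (PUK), and a random forest.  Min-max normalization is
fitted inside each training fold and applied to the held-out fold, so no
test information leaks into scaling.  Performance is scored from the
pooled out-of-fold confusion matrix: overall accuracy (percent),
sensitivity, specificity, Cohen's kappa, F-score, precision, and AUC from
out-of-fold continuous scores.  The elderly-like group is the positive
class throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

__all__ = [
    "ConfusionCounts",
    "ClassificationReport",
    "KNNClassifier",
    "PUKSVC",
    "puk_kernel",
    "make_classifier",
    "min_max_normalize",
    "knn_predict",
    "score_confusion",
    "cross_validate",
    "POSITIVE_LABEL",
]

#: Positive class for the sensitivity/specificity orientation.
POSITIVE_LABEL = "elderly"


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class ClassificationReport:
    """Pooled cross-validation outcome for one classifier and state."""

    accuracy: float  # percent
    sensitivity: float
    specificity: float
    kappa: float
    f_score: float
    precision: float
    auc: float
    confusion: ConfusionCounts
    classifier: str
    state: str = ""
    seed: int = 0
    fold_assignments: np.ndarray = field(default_factory=lambda: np.array([]))


def score_confusion(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy (percent), sensitivity, specificity, kappa, F-score and
    precision from confusion counts; undefined ratios are NaN with a
    warning."""
    if c.total <= 0:
        raise ValueError("confusion counts must describe at least one instance")

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reported as NaN")
            return float("nan")
        return num / den

    total = c.total
    acc = (c.tp + c.tn) / total * 100.0
    sen = ratio(c.tp, c.tp + c.fn, "sensitivity")
    spe = ratio(c.tn, c.tn + c.fp, "specificity")
    precision = ratio(c.tp, c.tp + c.fp, "precision")
    f_score = ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f_score")
    p_a = (c.tp + c.tn) / total
    p_b = ((c.tp + c.fn) * (c.tp + c.fp) + (c.tn + c.fp) * (c.tn + c.fn)) / total**2
    kappa = ratio(p_a - p_b, 1.0 - p_b, "kappa")
    return {
        "accuracy": acc,
        "sensitivity": sen,
        "specificity": spe,
        "kappa": kappa,
        "f_score": f_score,
        "precision": precision,
    }


def min_max_normalize(train: np.ndarray, apply_to: np.ndarray | None = None):
    """Scale features to [0, 1] by training min/max.

    Constant training columns map to 0; data scaled by the training ranges
    may fall outside [0, 1] and is deliberately not clipped.  Returns
    ``(train_scaled, applied_scaled, scaler)``.
    """
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ValueError("training set must be nonempty")
    scaler = MinMaxScaler(clip=False).fit(train)
    out = scaler.transform(apply_to) if apply_to is not None else None
    return scaler.transform(train), out, scaler


class KNNClassifier(ClassifierMixin, BaseEstimator):
    """K-nearest-neighbor majority vote with deterministic tie-breaking.

    Euclidean distance; distance ties are resolved by training-set order
    (stable sort) and vote ties toward the positive class.  Those two
    rules are why this is hand-rolled rather than delegated: off-the-shelf
    KNN implementations leave both unspecified.
    """

    def __init__(self, k: int = 3, positive_label=POSITIVE_LABEL):
        self.k = k
        self.positive_label = positive_label

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > X.shape[0]:
            raise ValueError(f"k={self.k} exceeds the {X.shape[0]} training vectors")
        self.X_ = X
        self.y_ = np.asarray(y)
        self.classes_ = np.unique(self.y_)
        return self

    def _neighbors(self, q: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(self.X_ - q, axis=1)
        return np.argsort(d, kind="stable")[: self.k]

    def predict(self, X):
        check_is_fitted(self, "X_")
        X = check_array(X, dtype=float)
        out = []
        for q in X:
            votes = self.y_[self._neighbors(q)]
            labels, counts = np.unique(votes, return_counts=True)
            winners = labels[counts == counts.max()]
            if len(winners) > 1 and self.positive_label in winners:
                out.append(self.positive_label)
            else:
                out.append(winners[0])
        return np.asarray(out)

    def predict_proba(self, X):
        """Vote fractions per class (``classes_`` order)."""
        check_is_fitted(self, "X_")
        X = check_array(X, dtype=float)
        proba = np.zeros((X.shape[0], len(self.classes_)))
        for i, q in enumerate(X):
            votes = self.y_[self._neighbors(q)]
            for j, cls in enumerate(self.classes_):
                proba[i, j] = np.mean(votes == cls)
        return proba


def puk_kernel(
    X: np.ndarray, Y: np.ndarray, omega: float = 1.0, sigma: float = 1.0
) -> np.ndarray:
    """Pearson VII universal kernel Gram matrix.

    K(x, y) = 1 / [1 + (2 sqrt(2^(1/omega) - 1) ||x - y|| / sigma)^2]^omega

    omega controls the peak shape (omega=1 is Lorentzian, large omega
    approaches a Gaussian) and sigma the half-width.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    sq = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(Y**2, axis=1)[None, :]
        - 2.0 * X @ Y.T
    )
    dist = np.sqrt(np.clip(sq, 0.0, None))
    scale = 2.0 * np.sqrt(2.0 ** (1.0 / omega) - 1.0) / sigma
    return 1.0 / (1.0 + (scale * dist) ** 2) ** omega


class PUKSVC(ClassifierMixin, BaseEstimator):
    """Support vector classifier with the Pearson VII universal kernel.

    Thin estimator around a precomputed-kernel SVC; ``rbf=True`` switches
    to a standard RBF kernel as a fallback.
    """

    def __init__(
        self, omega: float = 1.0, sigma: float = 1.0, C: float = 1.0, rbf: bool = False
    ):
        self.omega = omega
        self.sigma = sigma
        self.C = C
        self.rbf = rbf

    def _gram(self, X, Y):
        if self.rbf:
            sq = (
                np.sum(X**2, axis=1)[:, None]
                + np.sum(Y**2, axis=1)[None, :]
                - 2.0 * X @ Y.T
            )
            return np.exp(-np.clip(sq, 0.0, None) / (2.0 * self.sigma**2))
        return puk_kernel(X, Y, self.omega, self.sigma)

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.X_ = X
        self.svc_ = SVC(kernel="precomputed", C=self.C)
        self.svc_.fit(self._gram(X, X), y)
        self.classes_ = self.svc_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "svc_")
        X = check_array(X, dtype=float)
        return self.svc_.predict(self._gram(X, self.X_))

    def decision_function(self, X):
        check_is_fitted(self, "svc_")
        X = check_array(X, dtype=float)
        return self.svc_.decision_function(self._gram(X, self.X_))


def make_classifier(name: str, seed: int = 0, **kwargs) -> BaseEstimator:
    """Classifier factory: ``knn`` (k=3), ``svm`` (PUK), ``rf`` (100 trees,
    sqrt-feature subsampling, seeded)."""
    name = name.lower()
    if name == "knn":
        return KNNClassifier(k=kwargs.pop("k", 3), **kwargs)
    if name == "svm":
        return PUKSVC(**kwargs)
    if name == "rf":
        return RandomForestClassifier(
            n_estimators=kwargs.pop("trees", 100),
            max_features="sqrt",
            random_state=seed,
            **kwargs,
        )
    raise ValueError(f"unknown classifier {name!r}; expected knn, svm or rf")


def knn_predict(train_X, train_y, query, k: int = 3):
    """Label of one query vector under the k-nearest-neighbor rule."""
    clf = KNNClassifier(k=k).fit(np.asarray(train_X, dtype=float), train_y)
    return clf.predict(np.atleast_2d(np.asarray(query, dtype=float)))[0]


def _positive_scores(model, X, positive) -> np.ndarray:
    """Continuous score for the positive class: vote/tree fraction or SVM
    decision value."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, list(model.classes_).index(positive)]
    dec = model.decision_function(X)
    # SVC decision values are oriented toward classes_[1]
    return dec if model.classes_[1] == positive else -dec


def cross_validate(
    X,
    y,
    model: BaseEstimator | str = "knn",
    folds: int = 10,
    seed: int = 0,
    state: str = "",
    **model_kwargs,
) -> ClassificationReport:
    """Stratified k-fold cross-validation with fold-internal normalization.

    Folds are assigned deterministically from ``seed``; min-max scaling is
    fitted on each training fold only.  The report pools out-of-fold
    predictions into one confusion matrix and computes AUC from
    out-of-fold scores.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if isinstance(model, str):
        model = make_classifier(model, seed=seed, **model_kwargs)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {list(classes)}")
    if counts.min() < folds:
        raise ValueError(
            f"need at least {folds} instances per class for {folds}-fold CV"
        )
    positive = POSITIVE_LABEL if POSITIVE_LABEL in classes else classes[1]

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_of = np.full(len(y), -1)
    y_pred = np.empty(len(y), dtype=y.dtype)
    scores = np.empty(len(y), dtype=float)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {fold}: a class is absent from the training split")
        fold_of[te] = fold
        Xtr, Xte, _ = min_max_normalize(X[tr], X[te])
        fitted = clone(model).fit(Xtr, y[tr])
        y_pred[te] = fitted.predict(Xte)
        scores[te] = _positive_scores(fitted, Xte, positive)

    is_pos = y == positive
    pred_pos = y_pred == positive
    conf = ConfusionCounts(
        tp=int(np.sum(is_pos & pred_pos)),
        tn=int(np.sum(~is_pos & ~pred_pos)),
        fp=int(np.sum(~is_pos & pred_pos)),
        fn=int(np.sum(is_pos & ~pred_pos)),
    )
    measures = score_confusion(conf)
    auc = float(roc_auc_score(is_pos.astype(int), scores))
    return ClassificationReport(
        accuracy=measures["accuracy"],
        sensitivity=measures["sensitivity"],
        specificity=measures["specificity"],
        kappa=measures["kappa"],
        f_score=measures["f_score"],
        precision=measures["precision"],
        auc=auc,
        confusion=conf,
        classifier=type(model).__name__,
        state=state,
        seed=seed,
        fold_assignments=fold_of,
    )
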