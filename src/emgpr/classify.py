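"""Six movement classifiers, cross-validated evaluation, and timing.

Classifiers: linear discriminant analysis (LDA), k-nearest neighbour
(KNN, k=2, Euclidean, ties broken by the nearer neighbour), decision tree
(DT, Gini, unlimited depth), per-class Gaussian maximum-likelihood (MLE,
equal priors, full covariance with ridge fallback), RBF support vector
machine (SVM, inner-grid-searched C and gamma) and a 16-16 tanh
multilayer perceptron (MLP, L2-regularised with early stopping).  Inputs
for the distance/margin/gradient classifiers (KNN, SVM, MLP) are z-scored
with statistics learned on the training split.

Evaluation follows the per-subject protocol: stratified 10-fold
cross-validation within each subject, accuracies averaged over folds then
over subjects, with wall-clock train/test times recorded per fold.  Two
accuracy statistics are reported because they genuinely differ: the
TN-inclusive one-vs-rest class-wise accuracy, and the mean per-class
recall (the diagonal average of the row-normalised confusion matrix,
which is the statistic printed under performance matrices and whose
chance level for 11 classes is 100/11 = 9.09%).
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .signal_model import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CLASSIFIER_KINDS", "ClassifierConfig", "GaussianMLE", "TrainedModel",
    "train", "predict", "ConfusionMatrix", "classwise_accuracy", "mean_recall",
    "EvaluationReport", "cross_validate",
]

CLASSIFIER_KINDS = ("lda", "knn", "dt", "mle", "svm", "mlp")


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters for the six classifiers."""

    knn_k: int = 2
    dt_min_leaf: int = 1
    mle_ridge: float = 1e-6
    svm_c_grid: tuple[float, ...] = tuple(2.0 ** np.arange(-5, 16, 2))
    svm_gamma_grid: tuple[float, ...] = tuple(2.0 ** np.arange(-15, 4, 2))
    svm_inner_folds: int = 3
    mlp_hidden: tuple[int, ...] = (16, 16)
    mlp_alpha: float = 1e-3
    mlp_solver: str = "adam"
    mlp_learning_rate: float = 0.1
    mlp_momentum: float = 0.1
    mlp_max_iter: int = 400
    standardize: bool = True


class GaussianMLE(BaseEstimator, ClassifierMixin):
    """Per-class Gaussian maximum-likelihood classifier with equal priors.

    Each class is modelled by its sample mean and full ML covariance; a
    test point is assigned to the class with the largest Gaussian
    log-density.  A singular class covariance receives an isotropic ridge
    of ``ridge * trace / d`` with a warning.
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        d = X.shape[1]
        self.means_, self.chol_, self.logdet_ = [], [], []
        for cls in self.classes_:
            Xc = X[y == cls]
            mu = Xc.mean(axis=0)
            diff = Xc - mu
            cov = diff.T @ diff / len(Xc)
            try:
                chol = linalg.cholesky(cov, lower=True)
            except linalg.LinAlgError:
                eps = self.ridge * np.trace(cov) / d
                if eps <= 0:
                    eps = self.ridge
                logger.warning("singular covariance for class %s; ridge %.3g added", cls, eps)
                chol = linalg.cholesky(cov + eps * np.eye(d), lower=True)
            self.means_.append(mu)
            self.chol_.append(chol)
            self.logdet_.append(2.0 * np.sum(np.log(np.diag(chol))))
        return self

    def _log_likelihood(self, X):
        X = np.asarray(X, float)
        ll = np.empty((X.shape[0], len(self.classes_)))
        for k, (mu, chol, logdet) in enumerate(zip(self.means_, self.chol_, self.logdet_)):
            z = linalg.solve_triangular(chol, (X - mu).T, lower=True)
            ll[:, k] = -0.5 * (np.sum(z * z, axis=0) + logdet)
        return ll

    def predict(self, X):
        return self.classes_[np.argmax(self._log_likelihood(X), axis=1)]


def _build_estimator(kind: str, cfg: ClassifierConfig, seed: int):
    if kind == "lda":
        return LinearDiscriminantAnalysis()
    if kind == "knn":
        # k=2 with distance weights: when the two neighbours disagree the
        # nearer one wins, which is exactly the documented tie-break rule.
        est = KNeighborsClassifier(n_neighbors=cfg.knn_k, metric="euclidean", weights="distance")
    elif kind == "dt":
        return DecisionTreeClassifier(criterion="gini", min_samples_leaf=cfg.dt_min_leaf, random_state=seed)
    elif kind == "mle":
        return GaussianMLE(ridge=cfg.mle_ridge)
    elif kind == "svm":
        grid = {"C": list(cfg.svm_c_grid), "gamma": list(cfg.svm_gamma_grid)}
        est = GridSearchCV(SVC(kernel="rbf"), grid, cv=cfg.svm_inner_folds, n_jobs=None)
    elif kind == "mlp":
        kwargs = dict(
            hidden_layer_sizes=cfg.mlp_hidden,
            activation="tanh",
            alpha=cfg.mlp_alpha,
            solver=cfg.mlp_solver,
            max_iter=cfg.mlp_max_iter,
            early_stopping=True,
            random_state=seed,
        )
        if cfg.mlp_solver == "sgd":
            kwargs.update(learning_rate_init=cfg.mlp_learning_rate, momentum=cfg.mlp_momentum)
        est = MLPClassifier(**kwargs)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")
    if cfg.standardize:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


@dataclass
class TrainedModel:
    """A fitted classifier bound to the feature-column layout it was trained on."""

    kind: str
    estimator: object
    classes: np.ndarray
    column_names: tuple[str, ...]


def train(kind: str, fm: FeatureMatrix, config: ClassifierConfig | None = None, seed: int = 0) -> TrainedModel:
    """Fit one classifier on a feature matrix."""
    cfg = config or ClassifierConfig()
    classes, counts = np.unique(fm.labels, return_counts=True)
    if len(classes) < 2:
        logger.warning("training with a single class %r", classes[0] if len(classes) else None)
    est = _build_estimator(kind, cfg, seed)
    y = fm.labels.astype(str)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter from MLP on tiny folds
        est.fit(fm.values, y)
    return TrainedModel(kind, est, classes.astype(str), tuple(fm.column_names))


def predict(model: TrainedModel, fm: FeatureMatrix) -> np.ndarray:
    """Predict one label per window; the column layout must match training."""
    if tuple(fm.column_names) != model.column_names:
        raise ValueError("feature column layout differs from the training layout")
    return np.asarray(model.estimator.predict(fm.values), dtype=object)


# ---------------------------------------------------------------------------
# Confusion matrices and accuracy statistics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Class-by-class table: rows = intended movement, columns = detected.

    Built either from raw prediction counts or directly from an
    already-row-normalised percentage matrix (as printed in performance
    tables).
    """

    classes: tuple[str, ...]
    counts: np.ndarray | None = None
    percent_matrix: np.ndarray | None = None

    @classmethod
    def from_predictions(cls, y_true, y_pred, classes=None) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=object)
        y_pred = np.asarray(y_pred, dtype=object)
        if classes is None:
            classes = sorted(set(map(str, y_true)) | set(map(str, y_pred)))
        classes = tuple(str(c) for c in classes)
        idx = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[idx[str(t)], idx[str(p)]] += 1
        return cls(classes, counts=counts)

    @classmethod
    def from_percent(cls, matrix, classes) -> "ConfusionMatrix":
        return cls(tuple(map(str, classes)), percent_matrix=np.asarray(matrix, float))

    @property
    def n_total(self) -> int:
        if self.counts is None:
            raise ValueError("total count unavailable for a percentage-only matrix")
        return int(self.counts.sum())

    def percent(self) -> np.ndarray:
        """Row-normalised matrix in percent; empty rows stay zero."""
        if self.percent_matrix is not None:
            return self.percent_matrix
        row = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(row > 0, self.counts / row * 100.0, 0.0)
        return pct


def classwise_accuracy(cm: ConfusionMatrix) -> float:
    """One-vs-rest (TP+TN)/(TP+TN+FP+FN), averaged over classes, in percent."""
    if cm.counts is None:
        raise ValueError("class-wise accuracy needs raw counts")
    total = cm.counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    accs = []
    for i in range(len(cm.classes)):
        tp = cm.counts[i, i]
        fn = cm.counts[i, :].sum() - tp
        fp = cm.counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        accs.append((tp + tn) / total)
    return float(np.mean(accs) * 100.0)


def mean_recall(cm: ConfusionMatrix) -> float:
    """Mean of the diagonal of the row-normalised (percent) matrix.

    This is the average printed under performance matrices; classes with
    no test windows are excluded with a warning.
    """
    pct = cm.percent()
    if cm.counts is not None:
        present = cm.counts.sum(axis=1) > 0
        if not np.all(present):
            logger.warning("classes %s have no test windows; excluded from mean recall",
                           [c for c, p in zip(cm.classes, present) if not p])
        diag = np.diag(pct)[present]
    else:
        diag = np.diag(pct)
    return float(np.mean(diag))


# ---------------------------------------------------------------------------
# Cross-validated evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Cross-validated evaluation of one feature set / classifier combination."""

    kind: str
    classes: tuple[str, ...]
    mean_accuracy: float          # Eq.-style TN-inclusive class-wise accuracy, %
    std_accuracy: float
    mean_recall: float            # diagonal average of the pooled confusion, %
    per_subject_accuracy: dict[str, float]
    confusion: ConfusionMatrix
    train_time: float             # summed wall-clock seconds over folds
    test_time: float
    folds: int
    seed: int

    def summary(self) -> str:
        lines = [
            f"Classifier: {self.kind.upper()}  ({self.folds}-fold CV, seed {self.seed})",
            f"Mean class-wise accuracy: {self.mean_accuracy:.2f}%  (std over subjects {self.std_accuracy:.2f})",
            f"Mean per-class recall:    {self.mean_recall:.2f}%",
            f"Train time: {self.train_time:.3f} s   Test time: {self.test_time:.3f} s",
            "Performance matrix (rows = intended, columns = detected, %):",
        ]
        pct = self.confusion.percent()
        width = max(len(c) for c in self.classes)
        header = " " * (width + 1) + " ".join(f"{c[:6]:>6}" for c in self.classes)
        lines.append(header)
        for c, row in zip(self.classes, pct):
            lines.append(f"{c:>{width}} " + " ".join(f"{v:6.2f}" for v in row))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "classes": list(self.classes),
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "mean_recall": self.mean_recall,
            "per_subject_accuracy": self.per_subject_accuracy,
            "confusion_counts": self.confusion.counts.tolist(),
            "confusion_percent": np.round(self.confusion.percent(), 2).tolist(),
            "train_time": self.train_time,
            "test_time": self.test_time,
            "folds": self.folds,
            "seed": self.seed,
        }


def cross_validate(
    fms: FeatureMatrix | dict[str, FeatureMatrix],
    kind: str,
    folds: int = 10,
    seed: int = 0,
    config: ClassifierConfig | None = None,
) -> EvaluationReport:
    """Stratified k-fold cross-validation within each subject.

    ``fms`` is either one feature matrix or a mapping subject -> matrix.
    Fold accuracies are averaged per subject, then across subjects; the
    confusion counts are pooled over all folds and subjects.
    """
    cfg = config or ClassifierConfig()
    subjects = fms if isinstance(fms, dict) else {"s1": fms}
    all_classes = sorted({str(l) for fm in subjects.values() for l in fm.labels})

    per_subject: dict[str, float] = {}
    pooled = np.zeros((len(all_classes), len(all_classes)), dtype=int)
    train_time = test_time = 0.0
    for subject, fm in subjects.items():
        y = fm.labels.astype(str)
        _, class_counts = np.unique(y, return_counts=True)
        if class_counts.min() < folds:
            logger.warning("subject %s: some classes have fewer than %d windows; stratification is best-effort",
                           subject, folds)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        fold_accs = []
        for tr_idx, te_idx in skf.split(fm.values, y):
            fm_tr = FeatureMatrix(fm.values[tr_idx], fm.columns, fm.labels[tr_idx])
            fm_te = FeatureMatrix(fm.values[te_idx], fm.columns, fm.labels[te_idx])
            t0 = time.perf_counter()
            model = train(kind, fm_tr, cfg, seed)
            t1 = time.perf_counter()
            pred = predict(model, fm_te)
            t2 = time.perf_counter()
            train_time += t1 - t0
            test_time += t2 - t1
            cm = ConfusionMatrix.from_predictions(fm_te.labels, pred, all_classes)
            pooled += cm.counts
            fold_accs.append(classwise_accuracy(cm))
        per_subject[subject] = float(np.mean(fold_accs))

    accs = np.array(list(per_subject.values()))
    pooled_cm = ConfusionMatrix(tuple(all_classes), counts=pooled)
    return EvaluationReport(
        kind=kind,
        classes=tuple(all_classes),
        mean_accuracy=float(accs.mean()),
        std_accuracy=float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        mean_recall=mean_recall(pooled_cm),
        per_subject_accuracy=per_subject,
        confusion=pooled_cm,
        train_time=train_time,
        test_time=test_time,
        folds=folds,
        seed=seed,
    )
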