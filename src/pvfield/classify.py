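"""Classifier training, validation and evaluation for the binary
nearfield-present / farfield-only task.

The three manual beat classes collapse to a binary target: ``PV-NF`` and
``combined`` carry a nearfield component (positive class ``nearfield``),
``atrial-FF`` does not (``farfield``).  Four classifier families are
supported — decision tree, linear discriminant analysis, support vector
machine and k-nearest neighbours — each preceded by a per-feature
Gaussianising normalisation fitted on training rows only.

Validation follows the clinical design: patients (never beats) are split,
25% of patients are held out for the final performance estimate, and a
4-fold patient-grouped cross-validation runs on the remainder.  Confidence
intervals for the ROC/AUC come from class-stratified bootstrap resampling
of beats.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_curve
from sklearn.model_selection import GroupKFold, cross_val_predict, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .features import FEATURE_NAMES, FeatureVector
from .io import NEARFIELD_LABELS

__all__ = [
    "ALGORITHMS",
    "POSITIVE",
    "NEGATIVE",
    "GaussianizingScaler",
    "NearfieldClassifier",
    "ValidationScheme",
    "EvaluationReport",
    "BootstrapROC",
    "ForwardSelectionResult",
    "fit_normalization",
    "train_classifier",
    "forward_select",
    "run_validation",
    "bootstrap_roc",
    "classify_beat",
    "metrics_from_confusion",
    "binary_target",
    "save_model",
    "load_model",
]

ALGORITHMS = ("decision_tree", "lda", "svm", "knn")
POSITIVE = "nearfield"
NEGATIVE = "farfield"


def binary_target(labels: Sequence[str]) -> np.ndarray:
    """Map three-class beat labels onto the binary nearfield target."""
    return np.array(
        [POSITIVE if lab in NEARFIELD_LABELS else NEGATIVE for lab in labels]
    )


class GaussianizingScaler(TransformerMixin, BaseEstimator):
    """Per-feature log-then-z-score normalisation for skewed features.

    A feature whose training-sample skewness exceeds ``skew_threshold`` in
    magnitude (band powers and amplitudes typically do) is passed through
    ``log(x + eps)`` before centring and scaling to unit variance.  The log
    branch is only taken for non-negative features.  Parameters are frozen
    from the training data; the transform is invertible.

    Attributes
    ----------
    log_applied_ : ndarray of bool, shape (n_features,)
    center_, scale_ : ndarray, shape (n_features,)
    """

    def __init__(self, skew_threshold: float = 1.0, eps: float = 1e-12):
        self.skew_threshold = skew_threshold
        self.eps = eps

    def fit(self, X, y=None):
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        X = check_array(X, ensure_min_samples=2)
        self.n_features_in_ = X.shape[1]
        with warnings.catch_warnings():
            # constant columns trip scipy's precision warning; they are
            # rejected as zero-variance below
            warnings.simplefilter("ignore", RuntimeWarning)
            skew = stats.skew(X, axis=0)
        nonneg = X.min(axis=0) >= 0
        self.log_applied_ = (np.abs(skew) > self.skew_threshold) & nonneg
        Z = X.copy()
        Z[:, self.log_applied_] = np.log(Z[:, self.log_applied_] + self.eps)
        self.center_ = Z.mean(axis=0)
        self.scale_ = Z.std(axis=0, ddof=1)
        zero = self.scale_ <= 0
        if zero.any():
            j = int(np.argmax(zero))
            name = (
                self.feature_names_in_[j]
                if hasattr(self, "feature_names_in_")
                else f"column {j}"
            )
            raise ValueError(f"feature {name!r} has zero variance on the training data")
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_")
        X = check_array(X).copy()
        X[:, self.log_applied_] = np.log(X[:, self.log_applied_] + self.eps)
        return (X - self.center_) / self.scale_

    def inverse_transform(self, Z):
        check_is_fitted(self, "scale_")
        X = np.asarray(Z, dtype=float) * self.scale_ + self.center_
        X[:, self.log_applied_] = np.exp(X[:, self.log_applied_]) - self.eps
        return X


def fit_normalization(table: pd.DataFrame, features: Optional[Sequence[str]] = None,
                      skew_threshold: float = 1.0) -> GaussianizingScaler:
    """Fit the Gaussianising normalisation on a feature table."""
    features = list(features) if features is not None else FEATURE_NAMES
    return GaussianizingScaler(skew_threshold=skew_threshold).fit(table[features])


class NearfieldClassifier(ClassifierMixin, BaseEstimator):
    """Binary nearfield/farfield electrogram classifier.

    A scikit-learn estimator wrapping one of the four supported algorithm
    families behind the Gaussianising normalisation.  The decision score is
    oriented so that *higher means more nearfield-like* (the positive class
    is ``classes_[1]``, i.e. ``"nearfield"`` with the canonical string
    labels).

    Parameters
    ----------
    algorithm : {"svm", "lda", "knn", "decision_tree"}
    features : sequence of str, optional
        Column subset used when ``X`` is a DataFrame (default: all six).
    normalize : bool
        Fit a :class:`GaussianizingScaler` on the training rows (default).
    C, kernel : SVM hyperparameters (linear kernel, C=1 by default).
    n_neighbors : KNN neighbourhood size (default 5).
    max_depth : decision-tree depth cap (default 4).
    """

    def __init__(
        self,
        algorithm: str = "svm",
        features: Optional[Sequence[str]] = None,
        normalize: bool = True,
        C: float = 1.0,
        kernel: str = "linear",
        n_neighbors: int = 5,
        max_depth: int = 4,
        skew_threshold: float = 1.0,
        random_state: int = 0,
    ):
        self.algorithm = algorithm
        self.features = features
        self.normalize = normalize
        self.C = C
        self.kernel = kernel
        self.n_neighbors = n_neighbors
        self.max_depth = max_depth
        self.skew_threshold = skew_threshold
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _base_estimator(self):
        if self.algorithm == "svm":
            return SVC(kernel=self.kernel, C=self.C, random_state=self.random_state)
        if self.algorithm == "lda":
            return LinearDiscriminantAnalysis()  # pooled covariance
        if self.algorithm == "knn":
            return KNeighborsClassifier(n_neighbors=self.n_neighbors)
        if self.algorithm == "decision_tree":
            return DecisionTreeClassifier(
                max_depth=self.max_depth, random_state=self.random_state
            )
        raise ValueError(
            f"unknown algorithm {self.algorithm!r} (expected one of {ALGORITHMS})"
        )

    def _select(self, X):
        if hasattr(X, "columns"):
            cols = list(self.features) if self.features is not None else FEATURE_NAMES
            missing = [c for c in cols if c not in X.columns]
            if missing:
                raise ValueError(f"missing feature column(s) {missing}")
            return X[cols].to_numpy(dtype=float), cols
        return np.asarray(X, dtype=float), None

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X, cols = self._select(X)
        X, y = check_X_y(X, y)
        self.classes_ = unique_labels(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"need exactly two classes in the training data, got {self.classes_}"
            )
        self.feature_names_ = cols
        self.n_features_in_ = X.shape[1]
        steps = []
        if self.normalize:
            steps.append(("normalize", GaussianizingScaler(self.skew_threshold)))
        steps.append(("model", self._base_estimator()))
        self.pipeline_ = Pipeline(steps)
        self.pipeline_.fit(X, y)
        return self

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        X, _ = self._select(X)
        return self.pipeline_.predict(check_array(X))

    def decision_function(self, X):
        """Continuous score, larger for the positive (``classes_[1]``) class."""
        check_is_fitted(self, "pipeline_")
        X, _ = self._select(X)
        X = check_array(X)
        model = self.pipeline_[-1]
        if hasattr(model, "decision_function"):  # svm, lda
            score = self.pipeline_.decision_function(X)
        else:  # knn, tree: positive-class fraction
            proba = self.pipeline_.predict_proba(X)
            score = proba[:, list(model.classes_).index(self.classes_[1])]
        return np.asarray(score, dtype=float)

    @property
    def positive_class(self):
        check_is_fitted(self, "classes_")
        return self.classes_[1]


# ---------------------------------------------------------------------------
# training / selection wrappers operating on feature tables
# ---------------------------------------------------------------------------


def _table_Xy(table: pd.DataFrame, features: Sequence[str]):
    X = table[list(features)].to_numpy(dtype=float)
    y = binary_target(table["label"])
    return X, y


def train_classifier(
    table: pd.DataFrame,
    algorithm: str = "svm",
    feature_subset: Optional[Sequence[str]] = None,
    **hyperparameters,
) -> NearfieldClassifier:
    """Fit one classifier on a feature table (all rows are training rows)."""
    features = list(feature_subset) if feature_subset is not None else FEATURE_NAMES
    X, y = _table_Xy(table, features)
    if len(np.unique(y)) < 2:
        raise ValueError("training table contains a single class only")
    clf = NearfieldClassifier(algorithm=algorithm, features=features, **hyperparameters)
    clf.fit(table, y)
    return clf


@dataclass
class ForwardSelectionResult:
    selected: list[str]
    step_accuracy: list[float]  # CV accuracy (%) after each accepted step
    baseline_accuracy: float  # majority-class accuracy (%) of the empty model


def _cv_splitter(table: pd.DataFrame, cv_folds: int):
    groups = table["patient_id"].to_numpy()
    n_groups = len(np.unique(groups))
    return GroupKFold(n_splits=min(cv_folds, n_groups)), groups


def forward_select(
    table: pd.DataFrame,
    algorithm: str = "svm",
    cv_folds: int = 4,
    candidate_features: Optional[Sequence[str]] = None,
    stop_delta: float = 0.5,
    **hyperparameters,
) -> ForwardSelectionResult:
    """Greedy forward-wrapped feature selection on cross-validated accuracy.

    Starting from the empty set, each step adds the candidate that maximises
    patient-grouped cross-validated overall accuracy; selection stops when
    the best addition improves accuracy by no more than ``stop_delta``
    percentage points.  Ties break to the earlier candidate in list order.
    """
    candidates = list(candidate_features) if candidate_features else FEATURE_NAMES
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate features")
    y = binary_target(table["label"])
    cv, groups = _cv_splitter(table, cv_folds)

    def cv_accuracy(feats: list[str]) -> float:
        clf = NearfieldClassifier(algorithm=algorithm, features=feats, **hyperparameters)
        scores = cross_val_score(
            clf, table, y, groups=groups, cv=cv, scoring="accuracy"
        )
        return float(scores.mean() * 100.0)

    counts = pd.Series(y).value_counts()
    baseline = float(counts.max() / counts.sum() * 100.0)
    selected: list[str] = []
    step_acc: list[float] = []
    current = baseline
    remaining = list(candidates)
    while remaining:
        trial = [(cv_accuracy(selected + [f]), f) for f in remaining]
        best_acc = max(a for a, _ in trial)
        best_f = next(f for a, f in trial if a == best_acc)  # first wins ties
        if best_acc - current <= stop_delta:
            break
        selected.append(best_f)
        remaining.remove(best_f)
        step_acc.append(best_acc)
        current = best_acc
    return ForwardSelectionResult(selected, step_acc, baseline)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def metrics_from_confusion(tp: int, fn: int, fp: int, tn: int) -> dict:
    """Accuracy / sensitivity / specificity (percent) from confusion counts,
    with nearfield as the positive class."""
    n = tp + fn + fp + tn
    if n == 0:
        raise ValueError("empty confusion matrix")
    return {
        "accuracy": (tp + tn) / n * 100.0,
        "sensitivity": tp / (tp + fn) * 100.0 if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) * 100.0 if tn + fp else float("nan"),
    }


def _rank_auc(scores: np.ndarray, pos: np.ndarray) -> float:
    """Tie-averaged rank AUC (Mann-Whitney statistic): identical to the
    trapezoidal area under the empirical ROC, and exactly 1.0 for perfectly
    separated scores."""
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class BootstrapROC:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    level: float
    n_boot: int


def bootstrap_roc(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapROC:
    """Empirical ROC with a percentile-bootstrap AUC confidence interval.

    AUC is the trapezoidal area under the empirical ROC (equivalently the
    tie-averaged rank statistic).  Resampling is beat-level with replacement,
    stratified by class so every resample contains both classes.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels) == POSITIVE if np.asarray(labels).dtype.kind in "US" \
        else np.asarray(labels).astype(bool)
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present to build a ROC curve")
    fpr, tpr, thr = roc_curve(pos, scores)
    point_auc = _rank_auc(scores, pos)
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(pos)
    idx_neg = np.flatnonzero(~pos)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate(
            [
                rng.choice(idx_pos, size=idx_pos.size, replace=True),
                rng.choice(idx_neg, size=idx_neg.size, replace=True),
            ]
        )
        aucs[b] = _rank_auc(scores[take], pos[take])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    # percentile interval of a bounded statistic; clip keeps the point
    # estimate inside on degenerate (constant) resample distributions
    lo, hi = min(lo, point_auc), max(hi, point_auc)
    return BootstrapROC(fpr, tpr, thr, point_auc, float(lo), float(hi), level, n_boot)


@dataclass
class ValidationScheme:
    """Patient-level validation design: 4-fold grouped CV on the training
    patients, 25% of patients held out for the final estimate."""

    cv_folds: int = 4
    holdout_fraction: float = 0.25
    split_unit: str = "patient"
    seed: int = 0
    n_boot: int = 1000
    ci_level: float = 0.95
    scope: str = "holdout"  # or "pooled": out-of-fold CV + holdout predictions


@dataclass
class EvaluationReport:
    tp: int
    fn: int
    fp: int
    tn: int
    accuracy: float
    sensitivity: float
    specificity: float
    roc: Optional[BootstrapROC]
    per_vein_accuracy: dict
    n_beats: int
    n_patients: int
    cv_accuracy: float
    scope: str
    algorithm: str
    features: list[str]
    holdout_patients: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "algorithm": self.algorithm,
            "features": self.features,
            "scope": self.scope,
            "confusion": {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn},
            "accuracy": round(self.accuracy, 1),
            "sensitivity": round(self.sensitivity, 1),
            "specificity": round(self.specificity, 1),
            "cv_accuracy": round(self.cv_accuracy, 1),
            "n_beats": self.n_beats,
            "n_patients": self.n_patients,
            "per_vein_accuracy": {k: round(v, 1) for k, v in self.per_vein_accuracy.items()},
            "holdout_patients": self.holdout_patients,
        }
        if self.roc is not None:
            d["auc"] = round(self.roc.auc, 3)
            d["auc_ci"] = [round(self.roc.ci_low, 3), round(self.roc.ci_high, 3)]
            d["ci_level"] = self.roc.level
        return d

    def to_text(self) -> str:
        lines = [
            f"algorithm: {self.algorithm}  features: {', '.join(self.features)}",
            f"scope: {self.scope}  beats: {self.n_beats}  patients: {self.n_patients}",
            f"confusion (nearfield positive): TP={self.tp} FN={self.fn} "
            f"FP={self.fp} TN={self.tn}",
            f"accuracy {self.accuracy:.1f}%  sensitivity {self.sensitivity:.1f}%  "
            f"specificity {self.specificity:.1f}%",
            f"cross-validation accuracy {self.cv_accuracy:.1f}%",
        ]
        if self.roc is not None:
            lines.append(
                f"AUC {self.roc.auc:.3f} "
                f"({self.roc.ci_low:.3f} to {self.roc.ci_high:.3f}, "
                f"{self.roc.level:.0%} bootstrap CI, n_boot={self.roc.n_boot})"
            )
        for vein, acc in sorted(self.per_vein_accuracy.items()):
            lines.append(f"  {vein}: {acc:.1f}%")
        return "\n".join(lines)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    pos_t = y_true == POSITIVE
    pos_p = y_pred == POSITIVE
    tp = int(np.sum(pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    return tp, fn, fp, tn


def run_validation(
    table: pd.DataFrame,
    algorithm: str = "svm",
    feature_subset: Optional[Sequence[str]] = None,
    scheme: ValidationScheme | None = None,
    **hyperparameters,
) -> EvaluationReport:
    """Patient-level holdout + grouped cross-validation on a feature table.

    Patients are partitioned once (seeded): ``holdout_fraction`` of them are
    set aside and never touched by the cross-validation; the report's
    confusion counts, ROC and per-vein table come from model predictions on
    those holdout patients (``scope="holdout"``) or from holdout plus
    out-of-fold CV predictions (``scope="pooled"``).
    """
    scheme = scheme or ValidationScheme()
    features = list(feature_subset) if feature_subset is not None else FEATURE_NAMES
    if "patient_id" not in table.columns:
        raise ValueError("every beat must carry a patient_id")
    patients = np.array(sorted(table["patient_id"].unique()))
    rng = np.random.default_rng(scheme.seed)
    order = rng.permutation(len(patients))
    n_hold = max(1, int(round(scheme.holdout_fraction * len(patients))))
    holdout_patients = set(patients[order[:n_hold]])
    train_patients = set(patients[order[n_hold:]])
    assert not holdout_patients & train_patients, "patient leaked across the split"

    is_hold = table["patient_id"].isin(holdout_patients).to_numpy()
    train_tab = table.loc[~is_hold]
    hold_tab = table.loc[is_hold]
    y_train = binary_target(train_tab["label"])
    if len(np.unique(y_train)) < 2:
        raise ValueError("training patients contain a single class only")

    cv, groups = _cv_splitter(train_tab, scheme.cv_folds)
    proto = NearfieldClassifier(
        algorithm=algorithm, features=features, **hyperparameters
    )
    cv_acc = float(
        cross_val_score(
            clone(proto), train_tab, y_train, groups=groups, cv=cv, scoring="accuracy"
        ).mean()
        * 100.0
    )
    model = clone(proto).fit(train_tab, y_train)

    y_hold = binary_target(hold_tab["label"])
    pred_hold = model.predict(hold_tab)
    score_hold = model.decision_function(hold_tab)
    if scheme.scope == "pooled":
        pred_cv = cross_val_predict(
            clone(proto), train_tab, y_train, groups=groups, cv=cv
        )
        score_cv = cross_val_predict(
            clone(proto), train_tab, y_train, groups=groups, cv=cv,
            method="decision_function",
        )
        y_eval = np.concatenate([y_hold, y_train])
        pred = np.concatenate([pred_hold, pred_cv])
        score = np.concatenate([score_hold, score_cv])
        veins = np.concatenate([hold_tab["vein"], train_tab["vein"]])
    elif scheme.scope == "holdout":
        y_eval, pred, score = y_hold, pred_hold, score_hold
        veins = hold_tab["vein"].to_numpy()
    else:
        raise ValueError(f"unknown scope {scheme.scope!r}")

    tp, fn, fp, tn = _confusion(y_eval, pred)
    m = metrics_from_confusion(tp, fn, fp, tn)
    per_vein = {
        v: float(np.mean(pred[veins == v] == y_eval[veins == v]) * 100.0)
        for v in np.unique(veins)
    }
    roc = None
    if len(np.unique(y_eval)) == 2:
        roc = bootstrap_roc(
            score, y_eval, n_boot=scheme.n_boot, level=scheme.ci_level,
            seed=scheme.seed,
        )
    return EvaluationReport(
        tp=tp, fn=fn, fp=fp, tn=tn,
        accuracy=m["accuracy"], sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        roc=roc, per_vein_accuracy=per_vein,
        n_beats=int(len(y_eval)), n_patients=int(len(patients)),
        cv_accuracy=cv_acc, scope=scheme.scope, algorithm=algorithm,
        features=features,
        holdout_patients=sorted(holdout_patients),
    )


def classify_beat(model: NearfieldClassifier, fv: FeatureVector | dict) -> tuple[str, float]:
    """Label one beat with a fitted model. Returns ``(label, score)`` with
    the score oriented nearfield-positive; deterministic for a fixed model."""
    feats = model.feature_names_ or FEATURE_NAMES
    get = (lambda n: getattr(fv, n)) if not isinstance(fv, dict) else fv.__getitem__
    try:
        row = np.array([[float(get(n)) for n in feats]])
    except (AttributeError, KeyError) as exc:
        raise ValueError(f"feature vector is missing a model feature: {exc}") from exc
    label = model.predict(row)[0]
    score = float(model.decision_function(row)[0])
    return str(label), score


# ---------------------------------------------------------------------------
# model persistence (documented JSON schema; see docs/methods.md)
# ---------------------------------------------------------------------------


def save_model(model: NearfieldClassifier, table: pd.DataFrame, path: str | Path) -> Path:
    """Persist a fitted model with its training rows to JSON.

    Schema: ``{"schema": "pvfield-model/1", "algorithm", "params",
    "features", "training": {"X": [[...]], "y": [...]}}``.  Loading refits
    deterministically from the stored training rows, which reproduces the
    exact decision function for every supported algorithm family.
    """
    feats = model.feature_names_ or FEATURE_NAMES
    X = table[feats].to_numpy(dtype=float)
    y = binary_target(table["label"])
    doc = {
        "schema": "pvfield-model/1",
        "algorithm": model.algorithm,
        "params": {k: v for k, v in model.get_params().items() if k != "features"},
        "features": feats,
        "training": {"X": X.tolist(), "y": y.tolist()},
    }
    path = Path(path)
    path.write_text(json.dumps(doc) + "\n")
    return path


def load_model(path: str | Path) -> NearfieldClassifier:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != "pvfield-model/1":
        raise ValueError(f"unrecognised model schema in {path}")
    clf = NearfieldClassifier(features=doc["features"], **doc["params"])
    X = np.asarray(doc["training"]["X"], dtype=float)
    frame = pd.DataFrame(X, columns=doc["features"])
    clf.fit(frame, np.asarray(doc["training"]["y"]))
    return clf
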