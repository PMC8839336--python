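"""Binary stress classification and its evaluation.

Three classifier families (RBF-kernel SVM, random forest, decision tree)
are trained with k-fold cross-validated hyperparameter search, applied to
chronological block sequences, and post-processed by a relabel pass that
flips isolated labels.  Evaluation follows the leave-one-person-out
protocol, with sensitivity/specificity-based metrics, and recordings are
summarized by the percentage of blocks labeled "stress".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import LabeledFeatureSet, apply_minmax, features_to_matrix, fit_minmax

__all__ = ["ModelSpec", "MetricsReport", "StressSummary", "DEFAULT_GRIDS",
           "train", "predict_sequence", "relabel", "compute_metrics",
           "balanced_accuracy_pct", "geometric_mean_pct", "loso_evaluate",
           "stress_percentage"]

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm": {"C": [0.1, 1.0, 10.0, 100.0], "gamma": ["scale", 0.1, 1.0]},
    "random_forest": {"n_estimators": [100, 200], "max_features": ["sqrt", 0.5]},
    "decision_tree": {"max_depth": [3, 5, 10, None], "criterion": ["gini", "entropy"]},
}


@dataclass(frozen=True)
class ModelSpec:
    family: str = "svm"
    param_grid: dict[str, list] | None = None
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in DEFAULT_GRIDS:
            raise ValueError(f"unknown classifier family {self.family!r}")
        if self.cv_folds < 2:
            raise ValueError("need at least 2 CV folds")

    @property
    def grid(self) -> dict[str, list]:
        return self.param_grid if self.param_grid is not None else DEFAULT_GRIDS[self.family]


@dataclass(frozen=True)
class MetricsReport:
    """Classification metrics, in percent."""

    accuracy: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    geometric_mean: float


@dataclass(frozen=True)
class StressSummary:
    """Percentage of blocks labeled "stress", overall and per road section."""

    pct_positive_total: float
    pct_positive_by_section: dict[str, float]
    n_blocks: int


def _base_estimator(spec: ModelSpec):
    if spec.family == "svm":
        return SVC(kernel="rbf", random_state=spec.seed)
    if spec.family == "random_forest":
        return RandomForestClassifier(random_state=spec.seed)
    return DecisionTreeClassifier(random_state=spec.seed)


def train(spec: ModelSpec, X: np.ndarray, y: np.ndarray):
    """Fit a classifier with cross-validated hyperparameter selection.

    Returns the refit best estimator, with the selected hyperparameters in
    ``.best_params_``.  Fold counts are capped by the minority-class size.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training set must contain both classes")
    folds = int(min(spec.cv_folds, counts.min()))
    cv = StratifiedKFold(n_splits=max(2, folds), shuffle=True, random_state=spec.seed)
    search = GridSearchCV(_base_estimator(spec), spec.grid, cv=cv, n_jobs=None)
    search.fit(X, y)
    model = search.best_estimator_
    model.best_params_ = search.best_params_
    return model


def predict_sequence(model: Any, X: np.ndarray) -> np.ndarray:
    """One binary label per block, in chronological order."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        return np.empty(0, dtype=int)
    n_expected = getattr(model, "n_features_in_", X.shape[1])
    if X.shape[1] != n_expected:
        raise ValueError(f"expected {n_expected} features, got {X.shape[1]}")
    return np.asarray(model.predict(X), dtype=int)


def relabel(labels: np.ndarray) -> np.ndarray:
    """Flip isolated labels: a label whose two neighbors both carry the
    opposite value takes that value.

    One sequential left-to-right pass, reading the already-updated
    predecessor and the original successor; endpoints are never modified.
    This variant is idempotent and never increases the number of isolated
    singletons (verified exhaustively for short sequences).
    """
    labels = np.asarray(labels, dtype=int)
    out = labels.copy()
    for i in range(1, len(labels) - 1):
        if out[i - 1] == labels[i + 1] != out[i]:
            out[i] = out[i - 1]
    return out


def balanced_accuracy_pct(sensitivity: float, specificity: float) -> float:
    """Arithmetic mean of sensitivity and specificity (percent in, percent out)."""
    return (sensitivity + specificity) / 2.0


def geometric_mean_pct(sensitivity: float, specificity: float) -> float:
    """Geometric mean of sensitivity and specificity (percent in, percent out)."""
    return float(np.sqrt(sensitivity * specificity))


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """Accuracy, sensitivity, specificity, BA, and GM, in percent."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    if len(np.unique(y_true)) < 2:
        raise ValueError("undefined metrics: ground truth contains a single class")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    acc = 100.0 * (tp + tn) / len(y_true)
    return MetricsReport(accuracy=acc, sensitivity=sens, specificity=spec,
                         balanced_accuracy=balanced_accuracy_pct(sens, spec),
                         geometric_mean=geometric_mean_pct(sens, spec))


def loso_evaluate(
    datasets: list[LabeledFeatureSet], spec: ModelSpec
) -> tuple[dict[str, MetricsReport], MetricsReport, MetricsReport]:
    """Leave-one-person-out evaluation.

    For each subject: min-max scaler and classifier are fit on all other
    subjects' blocks, the held-out subject's predictions are relabeled, and
    metrics computed.  Returns (per-subject metrics, their arithmetic mean,
    pooled-confusion metrics).  Both aggregation orders are reported because
    the geometric mean does not commute with averaging.
    """
    subjects = sorted({d.subject_id for d in datasets})
    if len(subjects) < 2:
        raise ValueError("leave-one-person-out needs at least 2 subjects")
    per_subject: dict[str, MetricsReport] = {}
    pooled_true: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    for held in subjects:
        train_sets = [d for d in datasets if d.subject_id != held]
        test_sets = [d for d in datasets if d.subject_id == held]
        X_tr = np.vstack([features_to_matrix(d.vectors) for d in train_sets])
        y_tr = np.concatenate([d.labels for d in train_sets])
        scaler = fit_minmax(X_tr)
        model = train(spec, apply_minmax(scaler, X_tr), y_tr)
        y_true = np.concatenate([d.labels for d in test_sets])
        preds = [relabel(predict_sequence(model, apply_minmax(
            scaler, features_to_matrix(d.vectors)))) for d in test_sets]
        y_pred = np.concatenate(preds)
        per_subject[held] = compute_metrics(y_true, y_pred)
        pooled_true.append(y_true)
        pooled_pred.append(y_pred)
    mean = MetricsReport(**{
        f: float(np.mean([getattr(m, f) for m in per_subject.values()]))
        for f in ("accuracy", "sensitivity", "specificity",
                  "balanced_accuracy", "geometric_mean")
    })
    pooled = compute_metrics(np.concatenate(pooled_true), np.concatenate(pooled_pred))
    return per_subject, mean, pooled


def stress_percentage(
    labels: np.ndarray,
    blocks: list[tuple[float, float]],
    sections: list[tuple[float, float, str]] | None = None,
) -> StressSummary:
    """Percentage of blocks labeled 1, overall and per road section.

    A block belongs to the section containing its start time.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(blocks):
        raise ValueError("labels must align with blocks")
    if len(blocks) == 0:
        raise ValueError("no blocks to summarize")
    total = 100.0 * labels.sum() / len(labels)
    by_section: dict[str, float] = {}
    if sections:
        for start, end, tag in sections:
            idx = [i for i, (bs, _) in enumerate(blocks) if start <= bs < end]
            if idx:
                by_section[tag] = 100.0 * labels[idx].sum() / len(idx)
    return StressSummary(pct_positive_total=float(total),
                         pct_positive_by_section=by_section,
                         n_blocks=len(blocks))
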