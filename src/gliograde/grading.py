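"""Three-class grading with four classifier families and repeated hold-out.

Cases are split 75/25 (stratified by grade), 30 times with different random
states; every family sees the identical splits so comparisons are paired.
Hyperparameters are tuned by grid search with inner 5-fold stratified CV on
the training rows only; feature standardization is fitted on the training
rows inside the same pipeline, so no test-set statistics leak into training.

Reported metrics: accuracy, macro (and weighted) precision/recall/F1 as
mean +- SD over repeats, per-grade accuracy (class-conditional recall), and
the pooled 3x3 confusion matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import GridSearchCV, StratifiedKFold, StratifiedShuffleSplit
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from gliograde.synthetic import GRADES

DEFAULT_TRAIN_FRACTION = 0.75
DEFAULT_N_REPEATS = 30

# SVC(probability=True) is the pairwise-coupling calibration the explainer
# needs; sklearn 1.9 deprecates the flag in favour of a sigmod-calibrated
# wrapper, which is a different estimator — keep the flag, quiet the notice.
warnings.filterwarnings("ignore", message="The `probability` parameter",
                        category=FutureWarning)


@dataclass
class ModelSpec:
    """One classifier family with its hyperparameter grid."""

    family: str                       # "RF" | "GBDT" | "SVM" | "NN"
    grid: dict = field(default_factory=dict)
    standardize_features: bool = True

    def build(self, seed: int) -> Pipeline:
        if self.family == "RF":
            est = RandomForestClassifier(random_state=seed, n_jobs=1)
        elif self.family == "GBDT":
            est = GradientBoostingClassifier(random_state=seed)
        elif self.family == "SVM":
            # probability outputs (pairwise-coupling calibration) are needed
            # by the local explainer
            est = SVC(kernel="rbf", probability=True, random_state=seed)
        elif self.family == "NN":
            est = MLPClassifier(random_state=seed, max_iter=2000)
        else:
            raise ValueError(f"unknown model family {self.family!r}")
        steps = []
        if self.standardize_features:
            steps.append(("scale", StandardScaler()))
        steps.append(("model", est))
        return Pipeline(steps)


def default_model_specs() -> list[ModelSpec]:
    """The four families with their default (small, honest) grids."""
    return [
        ModelSpec("RF", {"model__n_estimators": [200, 500],
                         "model__max_depth": [None, 10]}),
        ModelSpec("GBDT", {"model__learning_rate": [0.05, 0.1],
                           "model__n_estimators": [100, 300]}),
        ModelSpec("SVM", {"model__C": [0.1, 1, 10, 100],
                          "model__gamma": ["scale", 0.01, 0.1]}),
        ModelSpec("NN", {"model__hidden_layer_sizes": [(16,), (64,)],
                         "model__alpha": [1e-4, 1e-2]}),
    ]


@dataclass
class SplitScheme:
    train_fraction: float = DEFAULT_TRAIN_FRACTION
    n_repeats: int = DEFAULT_N_REPEATS
    stratified: bool = True
    master_seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class CVMetrics:
    per_repeat: pd.DataFrame            # one row per repeat
    aggregate: dict                     # metric -> (mean, sd)
    per_grade_accuracy: dict            # grade -> fraction (pooled) or None
    confusion: np.ndarray               # pooled 3x3, rows = true grade
    classes: tuple[str, ...]
    prediction_log: pd.DataFrame        # case index, repeat, true, predicted, probs


def make_splits(n_cases: int, labels, scheme: SplitScheme) -> list[tuple[np.ndarray, np.ndarray]]:
    """Repeated stratified 75/25 partitions; per-repeat seeds from the master seed."""
    scheme.validate()
    labels = np.asarray(labels)
    if len(labels) != n_cases:
        raise ValueError("labels length must equal n_cases")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError(f"every class needs >= 2 cases; got {dict(zip(classes, counts))}")
    splits = []
    for rep in range(scheme.n_repeats):
        sss = StratifiedShuffleSplit(n_splits=1, train_size=scheme.train_fraction,
                                     random_state=scheme.master_seed + rep)
        train_idx, test_idx = next(sss.split(np.zeros(n_cases), labels))
        splits.append((np.sort(train_idx), np.sort(test_idx)))
    return splits


def tune_and_train(model: ModelSpec, X_train: pd.DataFrame, y_train,
                   seed: int = 0, inner_folds: int = 5):
    """Grid search with inner stratified CV on the training rows; refit the best."""
    pipe = model.build(seed)
    if not model.grid:
        return pipe.fit(X_train, y_train)
    # small training sets: inner folds cannot exceed the smallest class
    _, counts = np.unique(np.asarray(y_train), return_counts=True)
    inner_folds = max(2, min(inner_folds, int(counts.min())))
    inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, model.grid, cv=inner, n_jobs=1, refit=True)
    search.fit(X_train, y_train)
    return search


def _repeat_metrics(y_true, y_pred) -> dict:
    out = {"accuracy": float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))}
    for avg in ("macro", "weighted"):
        p, r, f, _ = precision_recall_fscore_support(y_true, y_pred, average=avg,
                                                     zero_division=0)
        out[f"precision_{avg}"] = float(p)
        out[f"recall_{avg}"] = float(r)
        out[f"f1_{avg}"] = float(f)
    return out


def evaluate(models: list[ModelSpec], table: pd.DataFrame, scheme: SplitScheme,
             feature_columns: list[str] | None = None,
             label_column: str = "grade") -> dict[str, CVMetrics]:
    """Evaluate every family on identical repeated splits (paired comparison)."""
    if feature_columns is None:
        feature_columns = [c for c in table.columns if c not in ("case_id", label_column)]
    X = table[feature_columns].reset_index(drop=True)
    y = table[label_column].to_numpy()
    classes = tuple(g for g in GRADES if g in set(y)) or tuple(np.unique(y))
    splits = make_splits(len(y), y, scheme)

    results: dict[str, CVMetrics] = {}
    for spec in models:
        rows, log_rows = [], []
        pooled = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for rep, (tr, te) in enumerate(splits):
            fitted = tune_and_train(spec, X.iloc[tr], y[tr],
                                    seed=scheme.master_seed + rep)
            y_pred = fitted.predict(X.iloc[te])
            proba = fitted.predict_proba(X.iloc[te]) if hasattr(fitted, "predict_proba") else None
            m = _repeat_metrics(y[te], y_pred)
            m["repeat"] = rep
            rows.append(m)
            pooled += confusion_matrix(y[te], y_pred, labels=list(classes))
            for i, idx in enumerate(te):
                entry = {"case_index": int(idx), "repeat": rep,
                         "true": y[idx], "predicted": y_pred[i]}
                if proba is not None:
                    fitted_classes = (fitted.best_estimator_ if hasattr(fitted, "best_estimator_")
                                      else fitted).classes_
                    for cls, p in zip(fitted_classes, proba[i]):
                        entry[f"p_{cls}"] = float(p)
                log_rows.append(entry)
        per_repeat = pd.DataFrame(rows)
        aggregate = {
            col: (float(per_repeat[col].mean()), float(per_repeat[col].std(ddof=1)))
            for col in per_repeat.columns if col != "repeat"
        }
        results[spec.family] = CVMetrics(
            per_repeat=per_repeat,
            aggregate=aggregate,
            per_grade_accuracy=per_grade_accuracy(pooled, classes),
            confusion=pooled,
            classes=classes,
            prediction_log=pd.DataFrame(log_rows),
        )
    return results


def per_grade_accuracy(cm: np.ndarray, classes=GRADES) -> dict:
    """Class-conditional recall per grade; empty rows reported as None."""
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    out = {}
    for i, grade in enumerate(classes):
        row_sum = cm[i].sum()
        out[grade] = float(cm[i, i] / row_sum) if row_sum > 0 else None
    return out


def external_validation(models: list[ModelSpec], train_table: pd.DataFrame,
                        holdout_table: pd.DataFrame, scheme: SplitScheme,
                        feature_columns: list[str] | None = None,
                        label_column: str = "grade") -> dict[str, dict]:
    """Score a fixed held-out set with each repeat's trained model.

    Analog of validating an extra case set against every one of the repeat
    models: each of the ``n_repeats`` models (trained on that repeat's
    training rows) predicts the untouched hold-out cases; reported as the
    mean +- SD of hold-out accuracy over repeats.
    """
    if feature_columns is None:
        feature_columns = [c for c in train_table.columns
                           if c not in ("case_id", label_column)]
    X = train_table[feature_columns].reset_index(drop=True)
    y = train_table[label_column].to_numpy()
    Xh = holdout_table[feature_columns].reset_index(drop=True)
    yh = holdout_table[label_column].to_numpy()
    splits = make_splits(len(y), y, scheme)
    out: dict[str, dict] = {}
    for spec in models:
        accs = []
        for rep, (tr, _) in enumerate(splits):
            fitted = tune_and_train(spec, X.iloc[tr], y[tr],
                                    seed=scheme.master_seed + rep)
            accs.append(float(np.mean(fitted.predict(Xh) == yh)))
        accs = np.asarray(accs)
        out[spec.family] = {"accuracy_mean": float(accs.mean()),
                            "accuracy_sd": float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
                            "per_repeat": accs.tolist()}
    return out
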