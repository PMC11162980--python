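"""Ablation experiment engine: imaging / clinical / union feature sets x
three classifiers x seeds, with training-only min-max scaling, seeded
5-fold CV hyperparameter search, micro-averaged AUC evaluation, and the
paired one-tailed t-test between the clinical and union models.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve, auc as sk_auc
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

__all__ = [
    "ScalerState",
    "CLINICAL_FEATURES",
    "minmax_fit",
    "minmax_apply",
    "micro_auc",
    "train_eval",
    "ablation_experiment",
    "paired_one_tailed_t",
    "MODEL_KINDS",
]

#: the clinical feature set: demographics plus baseline motor severity
CLINICAL_FEATURES = ["age", "sex", "disease_duration", "ledd", "updrs3_off"]

MODEL_KINDS = ("svm", "boosted_trees", "mlp")


@dataclass
class ScalerState:
    """Per-column training min/max; fitted on training rows only."""

    col_min: np.ndarray
    col_max: np.ndarray
    columns: list[str] | None = None


def minmax_fit(X_train: np.ndarray | pd.DataFrame) -> ScalerState:
    cols = list(X_train.columns) if isinstance(X_train, pd.DataFrame) else None
    arr = np.asarray(X_train, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need at least one training row")
    return ScalerState(arr.min(axis=0), arr.max(axis=0), cols)


def minmax_apply(state: ScalerState, X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """x' = (x - min) / (max - min); constant columns map to 0; values
    outside the training range are NOT clipped."""
    if not isinstance(state, ScalerState):
        raise ValueError("scaler state is not fitted")
    arr = np.asarray(X, dtype=float)
    span = state.col_max - state.col_min
    safe = np.where(span == 0, 1.0, span)
    out = (arr - state.col_min) / safe
    out[:, span == 0] = 0.0
    return out


def micro_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Micro-averaged ROC AUC: pool the one-vs-rest score columns and their
    indicator columns into one ROC. A binary task binarizes to a single
    positive-class column, so the micro average equals the standard AUC."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if s.ndim == 1:
        s = s[:, None]
        onehot = (y == y.max())[:, None].astype(float)
    else:
        onehot = np.eye(s.shape[1])[y]
    fpr, tpr, _ = roc_curve(onehot.ravel(), s.ravel())
    return float(sk_auc(fpr, tpr))


_GRIDS = {
    "svm": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01, 0.1]},
    "boosted_trees": {
        "max_depth": [2, 3],
        "learning_rate": [0.1, 0.3],
        "n_estimators": [50, 100],
    },
    "mlp": {"hidden_layer_sizes": [(32,), (64, 32)], "alpha": [1e-4, 1e-2]},
}


def _make_model(kind: str, seed: int):
    if kind == "svm":
        return SVC(kernel="rbf")
    if kind == "boosted_trees":
        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            verbosity=0,
            tree_method="exact",
        )
    if kind == "mlp":
        return MLPClassifier(random_state=seed, max_iter=500)
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


def _scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return model.decision_function(X)
    return model.predict_proba(X)[:, 1]


def fit_model(kind: str, X_train: np.ndarray, y_train: np.ndarray, seed: int):
    """Seeded 5-fold CV grid search, then refit on the full training set."""
    y = np.asarray(y_train).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    gs = GridSearchCV(
        _make_model(kind, seed), _GRIDS[kind], cv=cv, scoring="roc_auc", n_jobs=1
    )
    gs.fit(np.asarray(X_train, dtype=float), y)
    return gs.best_estimator_


def train_eval(
    kind: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    seed: int = 0,
) -> float:
    """Fit with CV-chosen hyperparameters and return the test micro-AUC."""
    model = fit_model(kind, X_train, y_train, seed)
    s = _scores(model, np.asarray(X_test, dtype=float))
    a = micro_auc(y_test, s)
    assert abs(a - roc_auc_score(np.asarray(y_test).astype(int), s)) < 1e-9
    return a


def paired_one_tailed_t(
    clinical_aucs: np.ndarray, union_aucs: np.ndarray
) -> tuple[float, float]:
    """Paired one-tailed t-test of union > clinical.

    d = union - clinical; t = mean(d) / (sd(d)/sqrt(n)), p the upper tail at
    n-1 df. Degenerate case sd(d) = 0: p = 0 if mean(d) > 0, p = 1 if
    mean(d) < 0, and p = 0.5 when the sets are identical.
    """
    c = np.asarray(clinical_aucs, dtype=float)
    u = np.asarray(union_aucs, dtype=float)
    if c.shape != u.shape or c.size < 2:
        raise ValueError("need paired samples of equal length >= 2")
    d = u - c
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        m = d.mean()
        p = 0.0 if m > 0 else (1.0 if m < 0 else 0.5)
        return (np.inf if m > 0 else (-np.inf if m < 0 else 0.0), p)
    t = d.mean() / (sd / np.sqrt(n))
    return float(t), float(stats.t.sf(t, df=n - 1))


def ablation_experiment(
    feature_sets: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    y_train: np.ndarray,
    y_test: np.ndarray,
    models: tuple[str, ...] = MODEL_KINDS,
    n_seeds: int = 10,
    seed0: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full grid of (feature set x model x seed) test AUCs.

    ``feature_sets`` maps a name (imaging / clinical / union) to unscaled
    (train, test) frames; min-max scaling is fitted per set on the training
    rows. Returns (tidy results, summary). The summary carries mean/sd per
    cell and, per model, the paired one-tailed p-value of union > clinical.
    """
    rows = []
    for set_name, (Xtr, Xte) in feature_sets.items():
        state = minmax_fit(Xtr)
        tr = minmax_apply(state, Xtr)
        te = minmax_apply(state, Xte)
        for kind in models:
            for s in range(n_seeds):
                a = train_eval(kind, tr, y_train, te, y_test, seed=seed0 + s)
                rows.append(
                    {"feature_set": set_name, "model": kind, "seed": seed0 + s, "auc": a}
                )
    results = pd.DataFrame(rows)
    summary_rows = []
    for kind in models:
        sub = results[results.model == kind]
        by = {
            name: sub[sub.feature_set == name].sort_values("seed").auc.to_numpy()
            for name in feature_sets
        }
        row = {"model": kind}
        for name, aucs in by.items():
            row[f"{name}_mean"] = aucs.mean()
            row[f"{name}_sd"] = aucs.std(ddof=1) if len(aucs) > 1 else 0.0
        if "clinical" in by and "union" in by and n_seeds >= 2:
            _, p = paired_one_tailed_t(by["clinical"], by["union"])
            row["p_union_gt_clinical"] = p
        summary_rows.append(row)
    return results, pd.DataFrame(summary_rows)
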