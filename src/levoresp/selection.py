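"""Sequential mRMR -> LASSO -> RFE feature-selection cascade.

The cascade mirrors the standard radiomics recipe: mutual-information based
minimum-redundancy maximum-relevance ranking keeps the top 50 features;
an L1-penalized linear model with a cross-validated penalty keeps the
features with non-zero coefficients; recursive feature elimination with an
L2-regularized logistic estimator picks the final count by 5-fold CV. The
whole cascade is repeated (10 times by default, varying the CV fold seeds)
and the final set is the intersection across repeats, falling back to a
majority vote when the intersection is empty. All fitting happens on
training rows only.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "mutual_information",
    "mrmr_rank",
    "lasso_select",
    "rfe_select",
    "run_sequential",
]


@dataclass
class SelectionConfig:
    mrmr_k: int = 50
    mi_bins: int = 5
    cv_folds: int = 5
    lasso_alpha_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-4, 1, 30)
    )
    rfe_max_features: int = 30
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mrmr_k < 1 or self.n_repeats < 1:
            raise ValueError("mrmr_k and n_repeats must be >= 1")


@dataclass
class SelectionResult:
    names: list[str]  # final surviving features, ordered
    importances: dict[str, float]  # signed RFE estimator coefficients
    per_repeat: list[list[str]]  # audit trail of final sets per repeat
    alphas: list[float]  # chosen LASSO alpha* per repeat
    majority_fallback: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "names": self.names,
                    "importances": self.importances,
                    "per_repeat": self.per_repeat,
                    "alphas": self.alphas,
                    "majority_fallback": self.majority_fallback,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        return cls(**d)


# ---------------------------------------------------------------------------
# mutual information


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency codes; low-cardinality integer-like data is kept as is."""
    x = np.asarray(x)
    uniq = np.unique(x)
    if len(uniq) <= bins:
        return np.searchsorted(uniq, x)
    qs = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(qs, x, side="right")


def _mi_codes(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (nats) of two integer code vectors."""
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb)
    n = a.size
    pj = joint / n
    pa = pj.sum(axis=1, keepdims=True)
    pb = pj.sum(axis=0, keepdims=True)
    nz = pj > 0
    return float((pj[nz] * np.log(pj[nz] / (pa @ pb)[nz])).sum())


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int = 5) -> float:
    """MI in nats between a feature column and labels (or another feature).

    Continuous inputs are discretized into equal-frequency bins first; a
    constant column has MI 0 with anything.
    """
    x, y = np.asarray(x), np.asarray(y)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    return _mi_codes(_discretize(x, bins), _discretize(y, bins))


def mrmr_rank(X: pd.DataFrame, y: np.ndarray, k: int, bins: int = 5) -> list[str]:
    """Greedy minimum-redundancy maximum-relevance ranking (MID criterion).

    Picks argmax I(f; y) first, then repeatedly the feature maximizing
    relevance minus mean MI with the already-selected set. Ties break by
    column order. Returns min(k, n_features) names in selection order.
    """
    if X.shape[1] == 0:
        raise ValueError("empty feature matrix")
    cols = list(X.columns)
    codes = [_discretize(X[c].to_numpy(), bins) for c in cols]
    ycode = _discretize(np.asarray(y), bins)
    relevance = np.array([_mi_codes(c, ycode) for c in codes])
    p = len(cols)
    k = min(k, p)
    selected: list[int] = []
    red_sum = np.zeros(p)
    alive = np.ones(p, dtype=bool)
    for _ in range(k):
        if selected:
            score = relevance - red_sum / len(selected)
        else:
            score = relevance.copy()
        score[~alive] = -np.inf
        pick = int(np.argmax(score))  # first max wins ties
        selected.append(pick)
        alive[pick] = False
        if alive.any():
            add = np.array(
                [_mi_codes(codes[j], codes[pick]) if alive[j] else 0.0 for j in range(p)]
            )
            red_sum += add
    return [cols[i] for i in selected]


# ---------------------------------------------------------------------------
# LASSO


def lasso_select(
    X: pd.DataFrame, y: np.ndarray, config: SelectionConfig, seed: int | None = None
) -> tuple[list[str], float]:
    """L1 selection: alpha* by seeded stratified 5-fold CV (mean squared
    error on the 0/1 labels), refit on all rows at alpha*, keep features with
    non-zero coefficients. Features are standardized internally."""
    seed = config.seed if seed is None else seed
    y = np.asarray(y, dtype=float)
    if len(X) < config.cv_folds * 2:
        raise ValueError("too few records for the CV folds")
    arr = StandardScaler().fit_transform(X.to_numpy(dtype=float))
    if np.all(arr == 0):
        return [], float(config.lasso_alpha_grid[0])
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(arr, y.astype(int)))
    errs = np.zeros(len(config.lasso_alpha_grid))
    for ai, alpha in enumerate(config.lasso_alpha_grid):
        for tr, va in folds:
            model = Lasso(alpha=alpha, max_iter=5000)
            model.fit(arr[tr], y[tr])
            errs[ai] += ((model.predict(arr[va]) - y[va]) ** 2).mean()
    alpha_star = float(config.lasso_alpha_grid[int(np.argmin(errs))])
    final = Lasso(alpha=alpha_star, max_iter=5000).fit(arr, y)
    names = [c for c, w in zip(X.columns, final.coef_) if abs(w) > 1e-10]
    return names, alpha_star


# ---------------------------------------------------------------------------
# RFE


def _logistic() -> LogisticRegression:
    # L2-regularized by default (ridge penalty, C = 1)
    return LogisticRegression(C=1.0, solver="lbfgs", max_iter=2000)


def rfe_elimination_order(X: np.ndarray, y: np.ndarray) -> list[int]:
    """Backward elimination trace: at each step refit the L2-logistic
    estimator and drop the column with the smallest |coefficient| (ties:
    the later column). Returns column indices in elimination order."""
    alive = list(range(X.shape[1]))
    order: list[int] = []
    while len(alive) > 1:
        model = _logistic().fit(X[:, alive], y)
        coefs = np.abs(model.coef_[0])
        worst_local = int(np.flatnonzero(coefs == coefs.min())[-1])
        order.append(alive.pop(worst_local))
    order.append(alive[0])
    return order


def rfe_select(
    X: pd.DataFrame, y: np.ndarray, config: SelectionConfig, seed: int | None = None
) -> tuple[list[str], dict[str, float]]:
    """RFE with an L2-logistic estimator, one feature dropped per iteration.

    The kept count is the candidate in 1..min(30, p) maximizing seeded
    5-fold CV AUC of the estimator on the top-ranked features (ties: the
    smaller count). Importances are the signed coefficients of the final
    refit."""
    seed = config.seed if seed is None else seed
    y = np.asarray(y).astype(int)
    cols = list(X.columns)
    if len(cols) == 0:
        return [], {}
    arr = StandardScaler().fit_transform(X.to_numpy(dtype=float))
    if len(cols) == 1:
        model = _logistic().fit(arr, y)
        return cols, {cols[0]: float(model.coef_[0][0])}
    order = rfe_elimination_order(arr, y)
    ranking = order[::-1]  # best-surviving first
    max_k = min(config.rfe_max_features, len(cols))
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(arr, y))
    best_k, best_score = 1, -np.inf
    for k in range(1, max_k + 1):
        idx = ranking[:k]
        scores = []
        for tr, va in folds:
            m = _logistic().fit(arr[np.ix_(tr, idx)], y[tr])
            s = m.decision_function(arr[np.ix_(va, idx)])
            if len(np.unique(y[va])) < 2:
                continue
            scores.append(roc_auc_score(y[va], s))
        score = float(np.mean(scores)) if scores else -np.inf
        if score > best_score + 1e-12:
            best_k, best_score = k, score
    idx = ranking[:best_k]
    final = _logistic().fit(arr[:, idx], y)
    names = [cols[i] for i in idx]
    importances = {n: float(w) for n, w in zip(names, final.coef_[0])}
    return names, importances


# ---------------------------------------------------------------------------
# full cascade


def run_sequential(
    X: pd.DataFrame, y: np.ndarray, config: SelectionConfig | None = None
) -> SelectionResult:
    """mRMR -> LASSO -> RFE, repeated ``n_repeats`` times with per-repeat CV
    seeds; the final set is the across-repeat intersection (majority vote of
    at least half the repeats when the intersection is empty, flagged)."""
    config = config or SelectionConfig()
    y = np.asarray(y)
    per_repeat: list[list[str]] = []
    alphas: list[float] = []
    importances_acc: dict[str, list[float]] = {}
    ranked = mrmr_rank(X, y, config.mrmr_k, config.mi_bins)  # deterministic
    for r in range(config.n_repeats):
        seed_r = config.seed + r
        lasso_names, alpha = lasso_select(X[ranked], y, config, seed=seed_r)
        alphas.append(alpha)
        if lasso_names:
            rfe_names, imps = rfe_select(X[lasso_names], y, config, seed=seed_r)
        else:
            rfe_names, imps = [], {}
        per_repeat.append(rfe_names)
        for n, w in imps.items():
            importances_acc.setdefault(n, []).append(w)
    counts: dict[str, int] = {}
    for names in per_repeat:
        for n in names:
            counts[n] = counts.get(n, 0) + 1
    inter = [n for n in per_repeat[0] if counts.get(n, 0) == config.n_repeats]
    fallback = False
    if not inter and any(per_repeat):
        fallback = True
        seen: list[str] = []
        for names in per_repeat:
            for n in names:
                if n not in seen:
                    seen.append(n)
        inter = [n for n in seen if counts[n] * 2 >= config.n_repeats]
    importances = {n: float(np.mean(importances_acc[n])) for n in inter}
    return SelectionResult(inter, importances, per_repeat, alphas, fallback)
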