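"""Bioactivity-prediction evaluation protocol: feature filtering, binary
one-activity-vs-rest framing, nested cross-validation with random
hyperparameter search, and ROC/AUROC scoring.

A BGC may encode a product with several activities (antibacterial, antifungal,
antitumor-or-cytotoxic), so each activity is framed as an independent binary
task.  Rare features (nonzero in fewer than 10 BGCs) are removed before any
fitting — inside each training split, never on the full data, so the held-out
fold stays untouched.  Model selection uses nested resampling: stratified
10-fold outer cross-validation, and within each outer training split a random
search (at most 50 draws) scored by 3-fold inner cross-validated AUROC.  The
mean outer-fold AUROC is the headline performance number.

The classifier itself is a pluggable contract (:class:`ScoringLearner`); two
reference learners ship with the package — a regularized logistic linear
scorer and a randomized tree ensemble — and any learner exposing the same
fit/score surface and a declared hyperparameter space can be evaluated.
"""

from __future__ import annotations

import hashlib
import pickle
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ScoringLearner",
    "LogisticLearner",
    "TreeEnsembleLearner",
    "CVResult",
    "filter_features",
    "roc_auc",
    "nested_cv",
]

MIN_FEATURE_SUPPORT = 10


def filter_features(
    matrix: pd.DataFrame | np.ndarray, min_support: int = MIN_FEATURE_SUPPORT
):
    """Drop features nonzero in fewer than ``min_support`` rows (column order kept)."""
    values = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    support = (values != 0).sum(axis=0)
    keep = support >= min_support
    if not keep.any():
        raise ValueError(f"no feature is present in >= {min_support} BGCs")
    if isinstance(matrix, pd.DataFrame):
        return matrix.loc[:, keep]
    return values[:, keep]


def roc_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUROC with the full threshold-swept (fpr, tpr) curve.

    Trapezoidal over tied score groups, so the area equals the Mann-Whitney
    probability that a random positive outscores a random negative, ties
    counted half.  Requires both classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute an AUROC")
    fpr, tpr, _ = _roc_curve(labels, scores)
    return float(_trapezoid_auc(fpr, tpr)), fpr, tpr


class ScoringLearner(Protocol):
    """Classifier contract for the evaluation protocol.

    ``param_space`` maps hyperparameter names to candidate-value lists (random
    search draws uniformly from each); ``fit`` trains on one split and returns
    self; ``decision_scores`` returns a real-valued score per row, higher
    meaning more likely positive.
    """

    param_space: Mapping[str, Sequence]

    def fit(self, X: np.ndarray, y: np.ndarray, random_state: int, **params): ...

    def decision_scores(self, X: np.ndarray) -> np.ndarray: ...


class LogisticLearner:
    """L2-regularized logistic linear scorer."""

    param_space = {"C": [0.001, 0.01, 0.1, 1.0, 10.0, 100.0]}

    def __init__(self) -> None:
        self._model: LogisticRegression | None = None

    def fit(self, X, y, random_state: int = 0, **params):
        self._model = LogisticRegression(
            C=params.get("C", 1.0), max_iter=2000, random_state=random_state
        )
        self._model.fit(X, y)
        return self

    def decision_scores(self, X) -> np.ndarray:
        assert self._model is not None, "fit first"
        return self._model.decision_function(X)

    def state_checksum(self) -> str:
        assert self._model is not None, "fit first"
        payload = pickle.dumps(
            (self._model.coef_.round(12), self._model.intercept_.round(12))
        )
        return hashlib.sha256(payload).hexdigest()


class TreeEnsembleLearner:
    """Randomized tree ensemble (bagged decision trees with feature subsampling)."""

    param_space = {
        "n_estimators": [50, 100, 200],
        "max_depth": [None, 3, 5, 10],
        "max_features": ["sqrt", 0.5, 1.0],
    }

    def __init__(self) -> None:
        self._model: RandomForestClassifier | None = None

    def fit(self, X, y, random_state: int = 0, **params):
        self._model = RandomForestClassifier(
            n_estimators=params.get("n_estimators", 100),
            max_depth=params.get("max_depth"),
            max_features=params.get("max_features", "sqrt"),
            random_state=random_state,
            n_jobs=1,
        )
        self._model.fit(X, y)
        return self

    def decision_scores(self, X) -> np.ndarray:
        assert self._model is not None, "fit first"
        return self._model.predict_proba(X)[:, 1]

    def state_checksum(self) -> str:
        assert self._model is not None, "fit first"
        return hashlib.sha256(pickle.dumps(self._model)).hexdigest()


@dataclass
class CVResult:
    """Outcome of one nested cross-validation run."""

    fold_aucs: list[float]
    chosen_params: list[dict]
    model_checksums: list[str]
    seed: int

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.fold_aucs))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fold": range(len(self.fold_aucs)),
                "auroc": self.fold_aucs,
                "params": [repr(p) for p in self.chosen_params],
            }
        )


def _draw_params(space: Mapping[str, Sequence], rng: np.random.Generator) -> dict:
    return {k: v[rng.integers(len(v))] for k, v in space.items()}


def nested_cv(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    learner: ScoringLearner,
    outer: int = 10,
    inner: int = 3,
    search_iters: int = 50,
    seed: int = 0,
    min_support: int = MIN_FEATURE_SUPPORT,
    outer_folds: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> CVResult:
    """Nested cross-validation with random hyperparameter search.

    Outer: stratified ``outer``-fold split (or explicit ``outer_folds``).  Per
    outer fold, up to ``search_iters`` hyperparameter draws are scored by
    ``inner``-fold cross-validated mean AUROC on the training split only; the
    best draw is refit on the whole training split and scored on the held-out
    fold.  Feature filtering is fit on each training split and merely applied
    to its test split, so no test information leaks into fitting.  Everything
    is driven by ``seed``: identical seeds give identical folds, draws, and
    fitted models.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(X) < 30:
        raise ValueError("need at least 30 instances for nested evaluation")
    counts = np.bincount(y, minlength=2)
    if counts.min() < outer:
        raise ValueError(
            f"minority class has {counts.min()} members; cannot stratify {outer} outer folds"
        )
    rng = np.random.default_rng(seed)
    if outer_folds is None:
        outer_cv = StratifiedKFold(n_splits=outer, shuffle=True, random_state=seed)
        outer_folds = list(outer_cv.split(X, y))

    fold_aucs, chosen, checksums = [], [], []
    for fold_idx, (train_idx, test_idx) in enumerate(outer_folds):
        X_tr_full, y_tr = X[train_idx], y[train_idx]
        # feature filter fit on the training split only
        support = (X_tr_full != 0).sum(axis=0)
        keep = support >= min_support
        if not keep.any():
            raise ValueError("feature filter removed every feature on a training split")
        X_tr = X_tr_full[:, keep]
        X_te = X[test_idx][:, keep]

        candidates = [_draw_params(learner.param_space, rng) for _ in range(search_iters)]
        inner_seed = int(rng.integers(2**31 - 1))
        inner_cv = StratifiedKFold(n_splits=inner, shuffle=True, random_state=inner_seed)
        inner_splits = list(inner_cv.split(X_tr, y_tr))
        best_params, best_score = None, -np.inf
        for params in candidates:
            scores = []
            for in_tr, in_te in inner_splits:
                if len(np.unique(y_tr[in_te])) < 2 or len(np.unique(y_tr[in_tr])) < 2:
                    raise ValueError("class absent from an inner fold; stratification failed")
                model = type(learner)().fit(
                    X_tr[in_tr], y_tr[in_tr], random_state=inner_seed, **params
                )
                aucv, _, _ = roc_auc(model.decision_scores(X_tr[in_te]), y_tr[in_te])
                scores.append(aucv)
            mean_inner = float(np.mean(scores))
            if mean_inner > best_score:
                best_params, best_score = params, mean_inner

        final = type(learner)().fit(X_tr, y_tr, random_state=inner_seed, **best_params)
        if len(np.unique(y[test_idx])) < 2:
            raise ValueError("class absent from an outer test fold; stratification failed")
        aucv, _, _ = roc_auc(final.decision_scores(X_te), y[test_idx])
        fold_aucs.append(aucv)
        chosen.append(dict(best_params))
        checksums.append(
            final.state_checksum()
            if hasattr(final, "state_checksum")
            else hashlib.sha256(pickle.dumps(final)).hexdigest()
        )
    return CVResult(fold_aucs, chosen, checksums, seed)
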