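"""Backup-capacity prediction from divergence features.

Pairs are described by [ka, identity, expression_divergence, go_div] and a
buffering label; an RBF-kernel SVM is evaluated by repeated stratified
3-fold cross-validation with fold-internal standardization and an inner
grid search, so no test-fold information leaks into training.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("ka", "identity", "expression_divergence", "go_div")
DEFAULT_GAMMA_GRID = (0.01, 0.1, 1.0, 10.0)
DEFAULT_COST_GRID = (0.1, 1.0, 10.0, 100.0)


class PredictError(ValueError):
    pass


@dataclass
class FeatureVector:
    pair_id: str
    features: np.ndarray  # ordered as FEATURE_NAMES
    label: bool


@dataclass
class CvResult:
    auc_mean: float
    auc_sd: float
    roc_points: list[tuple[float, float]]
    folds: int
    repeats: int
    seed: int
    fold_aucs: list[float] = field(default_factory=list)


def assemble_features(pairs: Iterable) -> tuple[list[FeatureVector], list[str]]:
    """Build feature vectors from pair records, pooling WGD and SSD.

    Pairs with any non-finite feature or a missing buffering flag are
    excluded and their ids returned.  Standardization is deliberately NOT
    applied here: it happens inside each training fold.
    """
    vectors: list[FeatureVector] = []
    excluded: list[str] = []
    for p in pairs:
        feats = np.array(
            [p.ka, p.identity, p.expression_divergence, p.go_div], dtype=float
        )
        if p.buffering is None or not np.all(np.isfinite(feats)):
            excluded.append(p.pair_id)
            continue
        vectors.append(FeatureVector(p.pair_id, feats, bool(p.buffering)))
    if excluded:
        logger.info("excluded %d pairs with incomplete features", len(excluded))
    labels = {v.label for v in vectors}
    if labels != {True, False}:
        raise PredictError("need both positive and negative examples")
    return vectors, excluded


def auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Probability that a random positive outranks a random negative
    (rank/Mann-Whitney statistic); ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise PredictError("AUC needs both classes")
    ranks = rankdata(scores)
    return (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def train_rbf_classifier(
    X: np.ndarray, y: np.ndarray, gamma: float, cost: float
) -> Callable[[np.ndarray], np.ndarray]:
    """Fit an RBF SVM and return its decision function (higher = more
    likely buffering).  Deterministic given data and hyperparameters."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise PredictError("training data contains a single class")
    clf = SVC(kernel="rbf", gamma=gamma, C=cost)
    clf.fit(X, y)
    return clf.decision_function


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    constant = sd == 0
    if constant.any():
        logger.warning("constant feature column(s) at indices %s", np.where(constant)[0])
        sd = np.where(constant, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def _inner_grid_search(
    X: np.ndarray,
    y: np.ndarray,
    gamma_grid: Sequence[float],
    cost_grid: Sequence[float],
    seed: int,
    inner_folds: int = 3,
) -> tuple[float, float]:
    """Pick (gamma, cost) by mean AUC over an inner stratified CV of the
    training fold only."""
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    best = (-math.inf, gamma_grid[0], cost_grid[0])
    splits = list(skf.split(X, y))
    for gamma, cost in product(gamma_grid, cost_grid):
        aucs = []
        for tr, te in splits:
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                continue
            Xtr, Xte = _standardize(X[tr], X[te])
            score = train_rbf_classifier(Xtr, y[tr], gamma, cost)(Xte)
            aucs.append(auc(score, y[te].astype(bool)))
        if aucs:
            mean = float(np.mean(aucs))
            if mean > best[0]:
                best = (mean, gamma, cost)
    return best[1], best[2]


def cross_validate(
    vectors: Sequence[FeatureVector],
    folds: int = 3,
    repeats: int = 10,
    seed: int = 0,
    feature_subset: Sequence[str] | None = None,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    cost_grid: Sequence[float] = DEFAULT_COST_GRID,
) -> CvResult:
    """Repeated stratified k-fold CV of the RBF classifier.

    Standardization statistics and hyperparameters are derived from the
    training folds only.  The ROC points come from the pooled out-of-fold
    scores of the first repeat (one random realization).
    """
    X = np.array([v.features for v in vectors], dtype=float)
    y = np.array([v.label for v in vectors], dtype=int)
    if feature_subset is not None:
        idx = [FEATURE_NAMES.index(name) for name in feature_subset]
        X = X[:, idx]
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise PredictError(
            f"class with {counts.min()} examples cannot be stratified into {folds} folds"
        )
    fold_aucs: list[float] = []
    first_scores = np.empty(len(y))
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for tr, te in skf.split(X, y):
            gamma, cost = _inner_grid_search(X[tr], y[tr], gamma_grid, cost_grid, seed + rep)
            Xtr, Xte = _standardize(X[tr], X[te])
            scores = train_rbf_classifier(Xtr, y[tr], gamma, cost)(Xte)
            fold_aucs.append(auc(scores, y[te].astype(bool)))
            if rep == 0:
                first_scores[te] = scores
    fpr, tpr, _ = roc_curve(y, first_scores)
    return CvResult(
        auc_mean=float(np.mean(fold_aucs)),
        auc_sd=float(np.std(fold_aucs, ddof=1)),
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        folds=folds,
        repeats=repeats,
        seed=seed,
        fold_aucs=[float(a) for a in fold_aucs],
    )
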