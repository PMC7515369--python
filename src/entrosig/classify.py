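"""k-NN classification over entropy features.

The study design: k-nearest neighbours with k = 3, stratified 10-fold
cross-validation, feature vectors of 1-5 entropy values where no two
features may come from the same algorithm family (a PEn order cannot be
combined with another PEn order).  Features are z-scored with statistics
fitted on the training folds only; majority votes that tie are resolved
by the class of the single nearest neighbour.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = ["ClassificationResult", "knn_cross_validate", "feature_combination_search",
           "column_family"]


def column_family(name: str) -> str:
    """Algorithm family of a feature column named like ``'SEn(m=2,r=0.2)'``."""
    return name.split("(", 1)[0]


@dataclass
class ClassificationResult:
    """Cross-validated k-NN outcome for one feature set."""

    features: tuple[str, ...]
    k: int
    folds: int
    fold_accuracies: tuple[float, ...]
    mean_accuracy: float
    pooled_accuracy: float
    seed: int
    n_dropped: int = 0

    def sort_key(self):
        # rank: higher mean accuracy, then smaller set, then name order
        return (-self.mean_accuracy, len(self.features), self.features)


def _knn_predict(train_x, train_y, test_x, k: int) -> np.ndarray:
    """Majority vote over the k nearest training points (Euclidean);
    ties go to the class of the single nearest neighbour."""
    nn = NearestNeighbors(n_neighbors=k).fit(train_x)
    _, idx = nn.kneighbors(test_x)
    votes = train_y[idx]  # (n_test, k), neighbours ordered by distance
    classes = np.unique(train_y)
    counts = (votes[:, :, None] == classes[None, None, :]).sum(axis=1)
    best = counts.max(axis=1)
    pred = np.empty(len(test_x), dtype=train_y.dtype)
    for i in range(len(test_x)):
        tied = classes[counts[i] == best[i]]
        if len(tied) == 1:
            pred[i] = tied[0]
        else:  # nearest neighbour whose class is among the tied ones
            pred[i] = next(v for v in votes[i] if v in tied)
    return pred


def knn_cross_validate(
    features: pd.DataFrame,
    labels,
    k: int = 3,
    folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
) -> ClassificationResult:
    """Stratified k-fold cross-validation of a k-NN classifier.

    Rows containing undefined (NaN) feature values are dropped (with a
    logged count).  When ``standardize`` is on, each feature is z-scored
    using the mean and SD of the training fold only.  Returns per-fold
    accuracies, their mean and the pooled accuracy over all held-out
    predictions; a fixed seed reproduces the folds exactly.
    """
    y = np.asarray(labels)
    x = features.to_numpy(dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    keep = ~np.isnan(x).any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d rows with undefined feature values", n_dropped)
        x, y = x[keep], y[keep]
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} members — fewer than {folds} folds; "
            f"reduce the fold count"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_acc = []
    pooled_correct = 0
    for train_idx, test_idx in skf.split(x, y):
        tr_x, te_x = x[train_idx], x[test_idx]
        if standardize:
            mu = tr_x.mean(axis=0)
            sd = tr_x.std(axis=0)
            sd[sd == 0] = 1.0
            tr_x = (tr_x - mu) / sd
            te_x = (te_x - mu) / sd
        pred = _knn_predict(tr_x, y[train_idx], te_x, k)
        correct = int((pred == y[test_idx]).sum())
        pooled_correct += correct
        fold_acc.append(correct / len(test_idx))
    return ClassificationResult(
        features=tuple(features.columns),
        k=k,
        folds=folds,
        fold_accuracies=tuple(fold_acc),
        mean_accuracy=float(np.mean(fold_acc)),
        pooled_accuracy=pooled_correct / len(y),
        seed=seed,
        n_dropped=n_dropped,
    )


def valid_feature_sets(columns, max_size: int):
    """All 1..max_size column combinations with pairwise-distinct
    algorithm families (the same-family exclusion rule)."""
    cols = list(columns)
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(cols, size):
            fams = [column_family(c) for c in combo]
            if len(set(fams)) == len(fams):
                yield combo


def feature_combination_search(
    features: pd.DataFrame,
    labels,
    max_size: int = 5,
    k: int = 3,
    folds: int = 10,
    seed: int = 0,
) -> list[ClassificationResult]:
    """Exhaustive k-NN evaluation of every valid feature combination.

    Combinations mixing two settings of the same algorithm family are
    excluded, so a full-size vector carries one feature per family.
    Results are ranked by mean accuracy (ties: smaller set, then column
    order); every combination is evaluated with the same seed, hence
    identical folds.
    """
    results = [
        knn_cross_validate(features[list(combo)], labels, k=k, folds=folds, seed=seed)
        for combo in valid_feature_sets(features.columns, max_size)
    ]
    return sorted(results, key=ClassificationResult.sort_key)
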