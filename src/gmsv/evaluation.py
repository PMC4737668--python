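"""Feature matrices and cross-validated graph classification.

Mined patterns turn each graph into a binary feature vector (pattern
present/absent); side-view features are min-max normalized and appended.
Classification follows the standard protocol for this problem family:
balanced classes, stratified 3-fold cross-validation, and a linear-kernel
SVM.  Two modes are provided:

* ``cross_validate`` scores a precomputed feature matrix;
* ``cross_validate_end_to_end`` re-mines patterns and rebuilds the
  guidance Laplacian inside every training fold, so test subjects never
  influence pattern selection (no leakage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skmetrics
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .graph_core import GraphDataset, SubgraphPattern, is_subgraph_isomorphic
from .search import mine_top_k
from .side_views import SideView, minmax_normalize

__all__ = [
    "FeatureMatrix",
    "feature_matrix",
    "augment_with_views",
    "balance_indices",
    "cross_validate",
    "cross_validate_end_to_end",
]


@dataclass
class FeatureMatrix:
    """m×n binary pattern-by-graph occurrence matrix."""

    X: np.ndarray
    patterns: list[SubgraphPattern] = field(default_factory=list)
    column_ids: list[str] = field(default_factory=list)

    @property
    def n_patterns(self) -> int:
        return self.X.shape[0]

    @property
    def n_graphs(self) -> int:
        return self.X.shape[1]


def feature_matrix(
    patterns: list[SubgraphPattern], dataset: GraphDataset
) -> FeatureMatrix:
    """Stack pattern indicator vectors row-wise (column j = graph j)."""
    n = len(dataset)
    for p in patterns:
        if p.n != n:
            raise ValueError("pattern indicator length does not match the dataset")
    X = (
        np.vstack([p.indicator for p in patterns])
        if patterns
        else np.zeros((0, n), dtype=np.int8)
    )
    return FeatureMatrix(X=X, patterns=list(patterns), column_ids=list(dataset.ids))


def augment_with_views(
    fm: FeatureMatrix, views: list[SideView] | None, *, normalize: bool = True
) -> np.ndarray:
    """Per-subject design matrix: binary pattern features ++ view features."""
    blocks = [fm.X.T.astype(float)]
    for view in views or []:
        if view.n != fm.n_graphs:
            raise ValueError(
                f"view '{view.name}' has {view.n} subjects, expected {fm.n_graphs}"
            )
        feats = minmax_normalize(view.features) if normalize else view.features
        blocks.append(feats)
    return np.hstack(blocks)


def balance_indices(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random undersampling of the majority class; returns sorted indices."""
    y = np.asarray(labels)
    pos = np.flatnonzero(y > 0)
    neg = np.flatnonzero(y < 0)
    size = min(pos.size, neg.size)
    keep = np.concatenate(
        [
            rng.choice(pos, size=size, replace=False),
            rng.choice(neg, size=size, replace=False),
        ]
    )
    return np.sort(keep)


def _fold_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    return {
        "accuracy": float(skmetrics.accuracy_score(y_true, y_pred)),
        "precision": float(
            skmetrics.precision_score(y_true, y_pred, pos_label=1, zero_division=0)
        ),
        "recall": float(
            skmetrics.recall_score(y_true, y_pred, pos_label=1, zero_division=0)
        ),
        "f1": float(skmetrics.f1_score(y_true, y_pred, pos_label=1, zero_division=0)),
    }


def _summarize(folds: list[dict[str, float]]) -> dict[str, float]:
    out = {k: float(np.mean([f[k] for f in folds])) for k in folds[0]}
    out["n_folds"] = len(folds)
    return out


def _make_classifier():
    # linear-kernel maximum-margin classifier at library-default regularization
    return SVC(kernel="linear", C=1.0)


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    folds: int = 3,
    seed: int | None = None,
) -> dict[str, float]:
    """Stratified k-fold CV of a linear SVM on precomputed features.

    Returns mean accuracy/precision/recall/F1 across folds.  Requires at
    least ``folds`` labeled subjects per class.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    for cls in (-1, 1):
        if (y == cls).sum() < folds:
            raise ValueError(f"need at least {folds} subjects of class {cls}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_scores = []
    for train, test in skf.split(X, y):
        clf = _make_classifier()
        clf.fit(X[train], y[train])
        fold_scores.append(_fold_metrics(y[test], clf.predict(X[test])))
    return _summarize(fold_scores)


def _pattern_features_on(
    patterns: list[SubgraphPattern], graphs: list
) -> np.ndarray:
    """Recompute pattern presence on arbitrary graphs via the oracle."""
    out = np.zeros((len(patterns), len(graphs)), dtype=float)
    for i, p in enumerate(patterns):
        for j, g in enumerate(graphs):
            out[i, j] = 1.0 if is_subgraph_isomorphic(p.graph, g) else 0.0
    return out


def cross_validate_end_to_end(
    dataset: GraphDataset,
    views: list[SideView] | None,
    k: int = 10,
    min_sup: float = 0.3,
    folds: int = 3,
    seed: int | None = None,
    *,
    include_view_features: bool = True,
    mine_kwargs: dict | None = None,
) -> dict[str, float]:
    """CV where mining and guidance are refit per training fold.

    For each fold: the training subjects' graphs, labels, and views build
    the guidance Laplacian and the top-k patterns; test-subject features
    are then computed by checking pattern containment in the held-out
    graphs.  View normalization statistics are fit on training rows only.
    """
    y = dataset.labels
    for cls in (-1, 1):
        if (y == cls).sum() < folds:
            raise ValueError(f"need at least {folds} subjects of class {cls}")
    views = views or []
    mine_kwargs = mine_kwargs or {}
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_scores = []
    for train, test in skf.split(np.zeros(len(dataset)), y):
        sub = dataset.subset(train)
        sub_views = [
            SideView(v.features[train], weight=v.weight, name=v.name) for v in views
        ]
        result = mine_top_k(sub, sub_views, k=k, min_sup=min_sup, **mine_kwargs)
        patterns = [sp.pattern for sp in result.selected]
        Xtr = np.vstack(
            [p.indicator.astype(float) for p in patterns]
        ).T if patterns else np.zeros((train.size, 0))
        Xte = _pattern_features_on(patterns, [dataset.graphs[j] for j in test]).T
        if include_view_features:
            for v in views:
                lo = v.features[train].min(axis=0)
                span = v.features[train].max(axis=0) - lo
                span[span == 0] = 1.0
                Xtr = np.hstack([Xtr, (v.features[train] - lo) / span])
                Xte = np.hstack([Xte, (v.features[test] - lo) / span])
        clf = _make_classifier()
        clf.fit(Xtr, y[train])
        fold_scores.append(_fold_metrics(y[test], clf.predict(Xte)))
    return _summarize(fold_scores)
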