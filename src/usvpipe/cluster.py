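"""Unsupervised k-means clustering of calls with elbow model selection.

Acoustic features are standardized per column and weighted by group --
frequency-, duration- and contour-derived parameters each carry weight 1
by default so the three aspects of a call contribute equally.  The number
of clusters is chosen by the elbow method: k-means is run for each
candidate k with seeded restarts, and the elbow is the k whose point on
the (normalized) inertia curve lies farthest from the chord joining the
curve's endpoints.

The per-k search keeps the best of ``replicates`` random restarts and a
warm start that splits the previous k's solution, which makes the inertia
curve non-increasing in k by construction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import FEATURE_GROUPS, FEATURE_NAMES, AcousticFeatureVector, features_to_matrix

DEFAULT_MAX_CLUSTERS = 50
DEFAULT_REPLICATES = 100

#: Column index -> feature-group name, fixed by the feature layout.
_GROUP_OF_COLUMN = {
    FEATURE_NAMES.index(name): group
    for group, names in FEATURE_GROUPS.items()
    for name in names
}


@dataclass
class ClusteringModel:
    """Result of one k-means run in standardized, weighted feature space."""

    k: int
    centroids: np.ndarray
    feature_weights: Dict[str, float]
    assignments: np.ndarray
    inertia: float
    inertia_curve: Optional[np.ndarray]
    seed: int


def weighted_feature_matrix(
    features: Sequence[AcousticFeatureVector],
    weights: Optional[Dict[str, float]] = None,
    normalize_groups: bool = False,
) -> np.ndarray:
    """Standardize each feature column, then scale it by its group weight.

    Groups are the frequency-, duration- and contour-derived parameters
    (see :data:`usvpipe.core.FEATURE_GROUPS`); all weights default to 1,
    leaving the standardized matrix unchanged.  With ``normalize_groups``
    each column is additionally divided by the square root of its group
    size, so a weight of 1 gives every *group* -- not every column -- the
    same total variance: the duration of a call (one column) then counts
    as much as its six frequency statistics.  The end-to-end clustering
    model uses this normalization.  A zero-variance column is left at 0
    after centering.
    """
    if len(features) == 0:
        raise ValueError("cannot build a feature matrix from zero calls")
    weights = dict(weights or {})
    unknown = set(weights) - set(FEATURE_GROUPS)
    if unknown:
        raise ValueError(f"unknown feature groups: {sorted(unknown)}")
    group_size = {g: len(names) for g, names in FEATURE_GROUPS.items()}
    X = features_to_matrix(features).astype(float)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    Z = np.where(std > 0, (X - mean) / np.where(std > 0, std, 1.0), 0.0)
    for col, group in _GROUP_OF_COLUMN.items():
        scale = weights.get(group, 1.0)
        if normalize_groups:
            scale /= np.sqrt(group_size[group])
        Z[:, col] *= scale
    return Z


def kmeans_cluster(
    matrix: np.ndarray,
    k: int,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    warm_start_centroids: Optional[np.ndarray] = None,
) -> ClusteringModel:
    """Best-of-``replicates`` k-means assignment; deterministic given seed."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of points ({n})")
    best = KMeans(n_clusters=k, n_init=replicates, random_state=seed).fit(matrix)
    if warm_start_centroids is not None and warm_start_centroids.shape[0] == k - 1:
        init = _split_centroids(matrix, warm_start_centroids)
        warm = KMeans(n_clusters=k, n_init=1, init=init, random_state=seed).fit(matrix)
        if warm.inertia_ < best.inertia_:
            best = warm
    return ClusteringModel(
        k=k,
        centroids=best.cluster_centers_,
        feature_weights={},
        assignments=best.labels_,
        inertia=float(best.inertia_),
        inertia_curve=None,
        seed=seed,
    )


def _split_centroids(matrix: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Previous solution's centroids plus the point farthest from them.

    Warm-starting Lloyd's algorithm from this configuration can only lower
    the objective relative to the (k-1)-solution, which guarantees a
    non-increasing inertia curve.
    """
    d2 = ((matrix[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2).min(axis=1)
    extra = matrix[int(np.argmax(d2))]
    return np.vstack([centroids, extra])


def inertia_curve(
    matrix: np.ndarray,
    max_clusters: int = DEFAULT_MAX_CLUSTERS,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
) -> Tuple[np.ndarray, List[ClusteringModel]]:
    """Best within-cluster sum of squares for k = 1..max_clusters."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n < 3:
        raise ValueError("clustering needs at least three points")
    kmax = min(max_clusters, n)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(kmax)]
    models: List[ClusteringModel] = []
    prev_centroids = None
    for k in range(1, kmax + 1):
        model = kmeans_cluster(
            matrix, k, replicates=replicates, seed=seeds[k - 1],
            warm_start_centroids=prev_centroids,
        )
        models.append(model)
        prev_centroids = model.centroids
    curve = np.array([m.inertia for m in models])
    return curve, models


def choose_k_elbow(
    matrix: np.ndarray,
    max_clusters: int = DEFAULT_MAX_CLUSTERS,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
) -> int:
    """Elbow-method k: farthest point of the inertia curve from its chord.

    The distance is measured on the log-inertia curve (axes normalized to
    [0, 1]): relative rather than absolute improvements define the elbow,
    so a small but compact cluster -- a rare call type -- still registers
    even though its absolute inertia contribution is tiny next to the
    dominant types.
    """
    curve, _ = inertia_curve(matrix, max_clusters, replicates, seed)
    return elbow_index(curve) + 1


def elbow_index(curve: np.ndarray, log_scale: bool = True) -> int:
    """Index of the elbow of a non-increasing curve (0-based).

    The curve is mapped to the unit square and the index farthest from the
    chord joining its endpoints is returned.  With ``log_scale`` the
    inertia axis is logarithmic (the default used by :func:`choose_k_elbow`);
    a curve that reaches zero falls back to the linear scale.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size == 1:
        return 0
    y = curve
    if log_scale and np.all(curve > 0):
        y = np.log(curve)
    x = np.linspace(0.0, 1.0, curve.size)
    span = y[0] - y[-1]
    y = (y - y[-1]) / span if span > 0 else np.zeros_like(y)
    # distance from (x, y) to the chord joining (0, y0) and (1, y_end)
    x0, y0, x1, y1 = 0.0, y[0], 1.0, y[-1]
    num = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0)
    return int(np.argmax(num))


def match_clusters_to_types(
    assignments: Sequence[int], true_labels: Sequence[str]
) -> dict:
    """Contingency table, majority-type mapping and per-cluster purity."""
    assignments = np.asarray(assignments)
    true_labels = np.asarray(true_labels, dtype=object)
    if assignments.size != true_labels.size:
        raise ValueError("assignments and labels must have equal length")
    contingency = pd.crosstab(
        pd.Series(assignments, name="cluster"), pd.Series(true_labels, name="call_type")
    )
    mapping = contingency.idxmax(axis=1).to_dict()
    purity = (contingency.max(axis=1) / contingency.sum(axis=1)).to_dict()
    return {"contingency": contingency, "mapping": mapping, "purity": purity}


__all__ = [
    "ClusteringModel",
    "weighted_feature_matrix",
    "kmeans_cluster",
    "inertia_curve",
    "choose_k_elbow",
    "elbow_index",
    "match_clusters_to_types",
    "DEFAULT_MAX_CLUSTERS",
    "DEFAULT_REPLICATES",
]
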