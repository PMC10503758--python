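"""Cluster discovery on topic-simplex embeddings.

K-means (k-means++ seeding, best of ``n_init`` restarts by inertia) on the
raw topic-proportion vectors with Euclidean distance, validated by mean
silhouette (cohesion vs separation) and the Dunn index (minimum inter-cluster
distance over maximum intra-cluster diameter). The cluster count is chosen to
maximize mean silhouette, with ties broken by higher Dunn and then by the
smaller k.

Silhouette conventions: a singleton cluster's point scores 0, and a 0/0
(coincident points) also scores 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import KMeans

__all__ = [
    "ClusterAssignment",
    "kmeans_fit",
    "silhouette",
    "dunn_index",
    "select_k",
]


@dataclass
class ClusterAssignment:
    k: int
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    mean_silhouette: float
    silhouettes: np.ndarray
    dunn: float
    seed: int
    n_init: int

    def to_frame(self, encounter_ids: Sequence[str] | None = None) -> pd.DataFrame:
        idx = pd.Index(encounter_ids, name="encounter_id") if encounter_ids is not None else None
        return pd.DataFrame({"cluster": self.labels, "silhouette": self.silhouettes}, index=idx)


def _as_array(embeddings) -> np.ndarray:
    if isinstance(embeddings, pd.DataFrame):
        return embeddings.to_numpy(dtype=float)
    return np.asarray(embeddings, dtype=float)


def kmeans_fit(
    embeddings,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> ClusterAssignment:
    """Fit k-means and attach silhouette and Dunn quality metrics.

    Deterministic given the seed; the returned solution is the best of
    ``n_init`` k-means++ restarts by inertia.
    """
    X = _as_array(embeddings)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 points to cluster")
    n_distinct = np.unique(X, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct points")
    if k < 2:
        raise ValueError("k must be >= 2")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, max_iter=max_iter,
                tol=tol, random_state=seed)
    labels = km.fit_predict(X)
    mean_s, per_s = silhouette(X, labels)
    try:
        dunn = dunn_index(X, labels)
    except ValueError:
        dunn = float("nan")
    return ClusterAssignment(
        k=k, labels=labels, centroids=km.cluster_centers_, inertia=float(km.inertia_),
        mean_silhouette=mean_s, silhouettes=per_s, dunn=dunn, seed=seed, n_init=n_init,
    )


def silhouette(embeddings, labels) -> tuple[float, np.ndarray]:
    """Per-point silhouette s = (b - a) / max(a, b) and its mean.

    a = mean intra-cluster distance (excluding self); b = smallest mean
    distance to another cluster. Euclidean. Singletons and 0/0 score 0.
    """
    X = _as_array(embeddings)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    members = {c: np.flatnonzero(labels == c) for c in uniq}
    s = np.zeros(len(X))
    for c in uniq:
        idx = members[c]
        if len(idx) == 1:
            s[idx[0]] = 0.0
            continue
        intra = cdist(X[idx], X[idx])
        a = intra.sum(axis=1) / (len(idx) - 1)
        b = np.full(len(idx), np.inf)
        for c2 in uniq:
            if c2 == c:
                continue
            d = cdist(X[idx], X[members[c2]]).mean(axis=1)
            b = np.minimum(b, d)
        denom = np.maximum(a, b)
        with np.errstate(invalid="ignore"):
            vals = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
        s[idx] = vals
    return float(s.mean()), s


def dunn_index(embeddings, labels) -> float:
    """Min inter-cluster point distance over max intra-cluster diameter."""
    X = _as_array(embeddings)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Dunn index requires at least 2 clusters")
    dist = squareform(pdist(X))
    members = [np.flatnonzero(labels == c) for c in uniq]
    max_diam = max(
        (dist[np.ix_(idx, idx)].max() if len(idx) > 1 else 0.0) for idx in members
    )
    min_inter = min(
        dist[np.ix_(members[i], members[j])].min()
        for i in range(len(uniq))
        for j in range(i + 1, len(uniq))
    )
    if max_diam == 0:
        if min_inter == 0:
            raise ValueError("Dunn index undefined: coincident clusters of coincident points")
        return float("inf")
    return float(min_inter / max_diam)


def select_k(
    embeddings,
    k_grid: Sequence[int],
    seed: int = 0,
    **fit_kwargs,
) -> tuple[int, pd.DataFrame]:
    """Choose the cluster count maximizing mean silhouette.

    Ties go to the higher Dunn index, then to the smaller k. Returns the
    chosen k and the full per-k metric table.
    """
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("k_grid is empty")
    if len(k_grid) == 1:
        warnings.warn(f"grid of size 1: k={k_grid[0]} chosen by default", stacklevel=2)
    rows = []
    for k in sorted(k_grid):
        fit = kmeans_fit(embeddings, k, seed=seed, **fit_kwargs)
        rows.append({"k": k, "mean_silhouette": fit.mean_silhouette,
                     "dunn": fit.dunn, "inertia": fit.inertia})
    table = pd.DataFrame(rows)
    ranked = table.sort_values(
        by=["mean_silhouette", "dunn", "k"], ascending=[False, False, True],
        kind="mergesort",
    )
    return int(ranked.iloc[0]["k"]), table
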