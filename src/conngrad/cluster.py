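"""Data-driven clustering of gradient space.

K-means and spectral clustering over selected gradients, with the number of
clusters chosen by mean silhouette coefficient (Euclidean distance).  When all
computed gradients enter the feature matrix they are standardized first —
gradient 1's much larger range would otherwise drown the later components; by
default no normalization is applied when clustering gradients 1–2 only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans, SpectralClustering
from sklearn.metrics import silhouette_score
from sklearn.neighbors import kneighbors_graph

from .exceptions import GraphConnectivityError, InvalidParameterError

__all__ = [
    "ClusterResult",
    "normalize_gradients",
    "kmeans_cluster",
    "spectral_cluster",
    "silhouette_select",
]

# Kaufman & Rousseeuw's rule of thumb: mean silhouette <= 0.5 indicates weak
# or artificial structure; the selected k is flagged accordingly.
WEAK_SILHOUETTE = 0.5


@dataclass
class ClusterResult:
    labels: np.ndarray
    k: int
    method: str
    silhouette_mean: float
    seed: int
    per_k_scores: pd.DataFrame | None = None
    weak: bool = False
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = np.unique(self.labels).size
        if present != self.k:
            raise InvalidParameterError(f"{present} distinct labels for k={self.k}")
        if not -1 <= self.silhouette_mean <= 1:
            raise InvalidParameterError("silhouette outside [-1, 1]")


def normalize_gradients(g, components=None, force_normalize: bool = False) -> np.ndarray:
    """Feature matrix from selected gradient components (1-based selection).

    Each selected component is standardized to zero mean / unit variance —
    except that the default two-gradient selection ``(1, 2)`` is passed through
    raw (standardization there would distort the gradients' native ranges, and
    two components do not suffer the range-domination problem), unless
    ``force_normalize`` is set.  Constant components are dropped with a warning.
    """
    if components is None:
        components = (1, 2)
    components = tuple(int(c) for c in components)
    if not components:
        raise InvalidParameterError("component selection is empty")
    cols = [g.gradient(c) for c in components]
    x = np.column_stack(cols)
    if set(components) == {1, 2} and not force_normalize:
        return x
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [components[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"dropping constant gradient component(s) {dropped}", stacklevel=2)
        x, sd = x[:, keep], sd[keep]
    return (x - x.mean(axis=0)) / sd


def kmeans_cluster(features: np.ndarray, k: int, seed: int = 0, n_init: int = 50) -> ClusterResult:
    """K-means with ``n_init`` restarts; best run by within-cluster sum of squares."""
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if not 2 <= k < n:
        raise InvalidParameterError(f"k must be in [2, {n - 1}], got {k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(features)
    labels = km.labels_
    sil = float(silhouette_score(features, labels)) if np.unique(labels).size > 1 else 0.0
    return ClusterResult(
        labels, k, "kmeans", sil, seed, params={"n_init": n_init, "inertia": float(km.inertia_)}
    )


def spectral_cluster(
    features: np.ndarray, k: int, seed: int = 0, n_neighbors: int = 15
) -> ClusterResult:
    """Spectral clustering on a nearest-neighbor graph (then k-means in the
    spectral embedding).  Handles non-convex cluster shapes k-means cannot."""
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if not 2 <= k < n:
        raise InvalidParameterError(f"k must be in [2, {n - 1}], got {k}")
    n_neighbors = min(n_neighbors, n - 1)
    graph = kneighbors_graph(features, n_neighbors=n_neighbors, include_self=False)
    n_comp, _ = connected_components(graph + graph.T, directed=False)
    if n_comp > k:
        # k or fewer components are fine (each becomes its own cluster);
        # more than k cannot be partitioned into k connected groups
        raise GraphConnectivityError(
            f"neighbor graph has {n_comp} components for k={k}; increase n_neighbors"
        )
    sc = SpectralClustering(
        n_clusters=k,
        affinity="nearest_neighbors",
        n_neighbors=n_neighbors,
        assign_labels="kmeans",
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*not fully connected.*")
        labels = sc.fit_predict(features)
    sil = float(silhouette_score(features, labels)) if np.unique(labels).size > 1 else 0.0
    return ClusterResult(labels, k, "spectral", sil, seed, params={"n_neighbors": n_neighbors})


def silhouette_select(
    features: np.ndarray,
    k_range=range(2, 9),
    method: str = "kmeans",
    seed: int = 0,
    **kwargs,
) -> ClusterResult:
    """Fit every k in ``k_range``; return the fit maximizing mean silhouette.

    Ties resolve to the smaller k (parsimony).  The full per-k score table is
    attached; a best score below {weak} flags the selection as weak structure.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise InvalidParameterError("k_range is empty")
    fit = kmeans_cluster if method == "kmeans" else spectral_cluster
    if method not in ("kmeans", "spectral"):
        raise InvalidParameterError(f"unknown method {method!r}")
    results = [fit(features, k, seed=seed, **kwargs) for k in ks]
    scores = [r.silhouette_mean for r in results]
    best = results[int(np.argmax(scores))]  # argmax takes the first (smallest k) on ties
    best.per_k_scores = pd.DataFrame({"k": ks, "silhouette_mean": scores})
    best.weak = best.silhouette_mean < WEAK_SILHOUETTE
    best.params = dict(best.params, k_range=ks, selection="max mean silhouette, ties to smaller k")
    return best


silhouette_select.__doc__ = silhouette_select.__doc__.format(weak=WEAK_SILHOUETTE)
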