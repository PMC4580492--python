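"""Exact K-medoids (PAM) clustering of catchments with silhouette k-selection.

Classic Partitioning Around Medoids: a greedy BUILD phase seeds k medoids by
successively adding the point that most reduces total dissimilarity, then a
SWAP phase accepts the best medoid/non-medoid exchange while any exchange
lowers total dissimilarity.  The objective strictly decreases at every
accepted swap over a finite configuration space, so termination is
guaranteed, and the result is deterministic given the input order.

Variables are z-scored before computing Euclidean dissimilarities — the 17
catchment variables span millimetres of rain, wells per square kilometre and
percentages, so raw distances would be dominated by precipitation.  The
number of clusters is chosen by maximal average silhouette width.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .registry import VariableSpec, default_registry, variable_names


@dataclasses.dataclass(frozen=True)
class ClusterResult:
    k: int
    medoid_indices: np.ndarray  # row indices into the clustered matrix
    labels: np.ndarray  # labels[i] in 0..k-1; label j means nearest medoid j
    total_dissimilarity: float
    avg_silhouette: float


def standardize(matrix: np.ndarray) -> np.ndarray:
    """Z-score columns; raises on a zero-variance column (uninformative for PAM)."""
    X = np.asarray(matrix, dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix contains missing entries")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant (zero-variance) column")
    return (X - X.mean(axis=0)) / sd


def _build(D: np.ndarray, k: int) -> list[int]:
    """Greedy seeding: repeatedly add the medoid that minimises total dissimilarity."""
    n = len(D)
    first = int(np.argmin(D.sum(axis=1)))
    medoids = [first]
    nearest = D[first].copy()
    while len(medoids) < k:
        # gain of adding candidate c: sum of max(0, nearest_j - D[j, c])
        gains = np.maximum(nearest[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))
        medoids.append(best)
        nearest = np.minimum(nearest, D[best])
    return medoids


def _swap(D: np.ndarray, medoids: list[int]) -> list[int]:
    """Best-improvement SWAP to a local optimum of total dissimilarity."""
    n = len(D)
    medoids = list(medoids)
    while True:
        med = np.array(medoids)
        dm = D[:, med]  # n x k distances to current medoids
        order = np.argsort(dm, axis=1)
        nearest_pos = order[:, 0]
        nearest = dm[np.arange(n), nearest_pos]
        second = dm[np.arange(n), order[:, 1]] if len(medoids) > 1 else np.full(n, np.inf)

        candidates = np.setdiff1d(np.arange(n), med, assume_unique=False)
        if candidates.size == 0:
            return medoids
        Dc = D[:, candidates]  # n x c

        best_delta, best_pair = 0.0, None
        for pos, i in enumerate(medoids):
            owned = nearest_pos == pos
            # points owned by i fall back to min(second, d(.,h)); others to
            # min(nearest, d(.,h))
            new_owned = np.minimum(second[owned, None], Dc[owned, :])
            new_other = np.minimum(nearest[~owned, None], Dc[~owned, :])
            delta = (new_owned - nearest[owned, None]).sum(axis=0)
            delta += (new_other - nearest[~owned, None]).sum(axis=0)
            j = int(np.argmin(delta))
            if delta[j] < best_delta - 1e-12:
                best_delta, best_pair = float(delta[j]), (pos, int(candidates[j]))
        if best_pair is None:
            return medoids
        medoids[best_pair[0]] = best_pair[1]


def _assign(D: np.ndarray, medoids: list[int]) -> tuple[np.ndarray, float]:
    dm = D[:, medoids]
    labels = np.argmin(dm, axis=1)
    return labels, float(dm[np.arange(len(D)), labels].sum())


#: below this many candidate medoid subsets the optimum is found by
#: enumeration instead of BUILD+SWAP (best-improvement SWAP can stall in a
#: local optimum even at n < 10, as can the reference R implementation)
EXACT_ENUMERATION_LIMIT = 10_000


def _exact(D: np.ndarray, k: int) -> list[int]:
    best_cost, best = np.inf, None
    for subset in itertools.combinations(range(len(D)), k):
        cost = D[:, subset].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best_cost, best = cost, subset
    return list(best)


def pam_cluster(
    matrix: np.ndarray,
    k: int,
    precomputed: np.ndarray | None = None,
    standardized: bool = False,
) -> ClusterResult:
    """K-medoids on z-scored Euclidean dissimilarities.

    Small instances (fewer than ``EXACT_ENUMERATION_LIMIT`` candidate medoid
    subsets) are solved exactly by enumeration; larger ones by greedy BUILD
    seeding followed by best-improvement SWAP to a local optimum.  Pass
    ``precomputed`` (a square dissimilarity matrix) to cluster on arbitrary
    dissimilarities; ``standardized=True`` skips the z-scoring.
    """
    if precomputed is not None:
        D = np.asarray(precomputed, dtype=float)
    else:
        X = np.asarray(matrix, dtype=float) if standardized else standardize(matrix)
        D = squareform(pdist(X))
    n = len(D)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, n]={n}, got {k}")
    from math import comb

    if comb(n, k) <= EXACT_ENUMERATION_LIMIT:
        medoids = _exact(D, k)
    else:
        medoids = _swap(D, _build(D, k))
    labels, total = _assign(D, medoids)
    sil = average_silhouette(labels, D) if len(set(labels)) > 1 else 0.0
    return ClusterResult(k, np.array(medoids), labels, total, sil)


def average_silhouette(labels: np.ndarray, dissimilarities: np.ndarray) -> float:
    """Mean silhouette width (b - a) / max(a, b) over all points.

    a is the mean dissimilarity to the point's own cluster (excluding
    itself), b the smallest mean dissimilarity to any other cluster.
    Singleton clusters contribute 0, and so do points with a = b = 0
    (identical points split across clusters).
    """
    labels = np.asarray(labels)
    D = np.asarray(dissimilarities, dtype=float)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    n = len(labels)
    s = np.zeros(n)
    cluster_sizes = {c: int((labels == c).sum()) for c in uniq}
    mean_to = np.stack([D[:, labels == c].sum(axis=1) for c in uniq], axis=1)
    for idx, c in enumerate(uniq):
        mean_to[:, idx] = np.where(
            labels == c,
            mean_to[:, idx] / max(cluster_sizes[c] - 1, 1),
            mean_to[:, idx] / cluster_sizes[c],
        )
    for i in range(n):
        own = np.where(uniq == labels[i])[0][0]
        if cluster_sizes[labels[i]] == 1:
            continue  # singleton: s = 0
        a = mean_to[i, own]
        b = np.min(np.delete(mean_to[i], own))
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def select_k(
    matrix: np.ndarray,
    k_range: range | list[int] = range(2, 16),
    precomputed: np.ndarray | None = None,
) -> tuple[int, ClusterResult]:
    """Cluster for each k and return the k with maximal average silhouette.

    Ties break toward smaller k.  Default range 2-15.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    if precomputed is None:
        X = standardize(matrix)
        precomputed = squareform(pdist(X))
    best: tuple[int, ClusterResult] | None = None
    for k in ks:
        result = pam_cluster(None, k, precomputed=precomputed)
        if best is None or result.avg_silhouette > best[1].avg_silhouette + 1e-12:
            best = (k, result)
    return best


def cluster_profiles(
    result: ClusterResult,
    table: pd.DataFrame,
    registry: dict[str, VariableSpec] | None = None,
) -> pd.DataFrame:
    """Per-cluster catchment counts and variable means (cluster descriptions)."""
    registry = registry if registry is not None else default_registry()
    if len(result.labels) != len(table):
        raise ValueError("labels do not align with table rows")
    names = [v for v in variable_names(registry) if v in table.columns]
    df = table[names].copy()
    df["cluster"] = result.labels
    prof = df.groupby("cluster").mean()
    prof.insert(0, "n", df.groupby("cluster").size())
    return prof.reset_index()
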