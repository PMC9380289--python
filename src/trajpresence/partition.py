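"""k-means partitioning of the point cloud.

The cloud is partitioned into k homogeneous regions and the region centers
become the nodes of the minimum spanning tree.  Lloyd iterations with
k-means++ seeding and multiple restarts; the implementation is written here
rather than delegated so that three contracts hold exactly: bit-level
determinism given a seed, invariance of the result under row shuffling of
the input, and a guarantee that all k clusters are non-empty (the tree
needs exactly k nodes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CenterSet", "DegenerateDataError", "kmeans_centers"]

_MAX_ITER = 300


class DegenerateDataError(ValueError):
    """The data cannot support the requested number of clusters."""


@dataclass(frozen=True)
class CenterSet:
    """k cluster centers with the size of each cluster.

    ``centers`` is k x d; ``sizes`` are positive and sum to n.  ``labels``
    carries the implied assignment of each observation (in the caller's row
    order); ``inertia`` is the within-cluster sum of squared distances.
    """

    centers: np.ndarray
    k: int
    sizes: np.ndarray
    labels: np.ndarray
    inertia: float

    def __post_init__(self):
        centers = np.asarray(self.centers, dtype=float)
        sizes = np.asarray(self.sizes, dtype=np.int64)
        if centers.shape[0] != self.k or sizes.shape[0] != self.k:
            raise ValueError("centers/sizes length != k")
        if np.any(sizes < 1):
            raise ValueError("empty cluster in CenterSet")
        centers.setflags(write=False)
        sizes.setflags(write=False)
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "sizes", sizes)


def _pairwise_sq(points: np.ndarray, centers: np.ndarray,
                 p_sq: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, n x k, clipped at 0."""
    d2 = p_sq[:, None] + np.einsum("kd,kd->k", centers, centers)[None, :]
    d2 -= 2.0 * points @ centers.T
    np.maximum(d2, 0.0, out=d2)
    return d2


def _seed_plus_plus(points: np.ndarray, p_sq: np.ndarray, k: int,
                    rng: np.random.Generator) -> np.ndarray:
    """k-means++ D^2 seeding over a canonically ordered point set."""
    n = points.shape[0]
    idx = np.empty(k, dtype=np.int64)
    idx[0] = rng.integers(n)
    closest = _pairwise_sq(points, points[idx[0]][None, :], p_sq)[:, 0]
    for j in range(1, k):
        total = closest.sum()
        if total <= 0.0:
            # all remaining points coincide with chosen centers
            remaining = np.setdiff1d(np.arange(n), idx[:j],
                                     assume_unique=False)
            idx[j] = remaining[0] if remaining.size else idx[0]
        else:
            # inverse-CDF draw over the cumulative D^2 weights
            u = rng.random() * total
            idx[j] = np.searchsorted(np.cumsum(closest), u, side="right")
            idx[j] = min(idx[j], n - 1)
        cand = _pairwise_sq(points, points[idx[j]][None, :], p_sq)[:, 0]
        np.minimum(closest, cand, out=closest)
    return idx


def _lloyd(points: np.ndarray, p_sq: np.ndarray, centers: np.ndarray,
           k: int) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """Lloyd iterations; returns (centers, labels, inertia, ss_history).

    Ties in nearest-center assignment break to the lowest center index
    (argmin convention).  A cluster that empties is re-seeded at the point
    farthest from its currently assigned center.
    """
    n, d = points.shape
    labels = np.full(n, -1, dtype=np.int64)
    history: list[float] = []
    for _ in range(_MAX_ITER):
        d2 = _pairwise_sq(points, centers, p_sq)
        new_labels = np.argmin(d2, axis=1)
        point_d2 = d2[np.arange(n), new_labels]
        counts = np.bincount(new_labels, minlength=k)
        while np.any(counts == 0):
            empty = int(np.argmin(counts))
            far = int(np.argmax(point_d2))
            new_labels[far] = empty
            point_d2[far] = 0.0
            counts = np.bincount(new_labels, minlength=k)
        history.append(float(point_d2.sum()))
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        sums = np.zeros((k, d))
        np.add.at(sums, labels, points)
        centers = sums / counts[:, None]
    d2 = _pairwise_sq(points, centers, p_sq)
    labels = np.argmin(d2, axis=1)
    inertia = float(d2[np.arange(n), labels].sum())
    return centers, labels, inertia, history


def kmeans_centers(X, k: int, seed, n_restarts: int = 10,
                   return_history: bool = False):
    """Cluster the rows of ``X`` into k groups and return the centers.

    ``X`` may be a DataMatrix or a plain n x d array.  ``seed`` is an
    integer or a :class:`numpy.random.SeedSequence`; restart r draws its
    randomness from the child stream ``(seed, r)``, so every cell of the
    permutation pipeline is independently reproducible.  The best of
    ``n_restarts`` runs (lowest within-cluster sum of squares, ties to the
    earliest restart) is returned.

    Rows are processed in a canonical (lexicographically sorted) order
    internally, which makes the result invariant under row shuffling of the
    input; returned labels are in the caller's row order.

    Raises
    ------
    ValueError
        If k < 3 (an MST on fewer than 3 nodes carries no shape signal).
    DegenerateDataError
        If X has fewer than k distinct rows.
    """
    points = np.asarray(getattr(X, "values", X), dtype=float)
    if points.ndim != 2:
        raise ValueError("X must be 2-D")
    n = points.shape[0]
    if k < 3:
        raise ValueError(f"k must be >= 3, got {k}")
    if k > n:
        raise DegenerateDataError(f"k={k} exceeds n={n}")
    n_distinct = np.unique(points, axis=0).shape[0]
    if n_distinct < k:
        raise DegenerateDataError(
            f"only {n_distinct} distinct rows for k={k} clusters")

    # canonical row order: first column primary, then the rest
    order = np.lexsort(points.T[::-1])
    sorted_pts = np.ascontiguousarray(points[order])
    p_sq = np.einsum("nd,nd->n", sorted_pts, sorted_pts)

    base = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(int(seed))
    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(
            np.random.SeedSequence(base.entropy, spawn_key=base.spawn_key + (r,)))
        init = sorted_pts[_seed_plus_plus(sorted_pts, p_sq, k, rng)]
        centers, labels, inertia, history = _lloyd(
            sorted_pts, p_sq, init.copy(), k)
        if best is None or inertia < best[2]:
            best = (centers, labels, inertia, history)

    centers, sorted_labels, inertia, history = best
    labels = np.empty(n, dtype=np.int64)
    labels[order] = sorted_labels
    sizes = np.bincount(labels, minlength=k)
    result = CenterSet(centers=centers, k=k, sizes=sizes, labels=labels,
                       inertia=inertia)
    if return_history:
        return result, history
    return result
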