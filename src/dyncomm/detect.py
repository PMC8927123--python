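"""Detection of nearly equitable partitions (dynamical communities).

A divisive variant of the Belykh–Hasler refinement for weighted networks:
at each step the cluster-degree rows of the current partition are compared
with a Euclidean dissimilarity, and k-medoids is applied to the
dissimilarity matrix with one more cluster than before.  Sweeping
k = 2..N-1 yields a candidate partition for every cluster count; the
correction-cost module scores them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .exact import cluster_degree_matrix
from .network import Partition, WeightedNetwork

__all__ = [
    "dissimilarity_matrix",
    "kmedoids",
    "KMedoidsResult",
    "SweepResult",
    "dynamical_communities_sweep",
]


def dissimilarity_matrix(P: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between cluster-degree rows:
    D[i, j] = ||P_i - P_j||_2.  Symmetric, zero diagonal."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    return squareform(pdist(P, metric="euclidean"))


def _seed_tuple(seed) -> tuple[int, ...]:
    if seed is None:
        return (0,)
    if np.isscalar(seed):
        return (int(seed),)
    return tuple(int(s) for s in seed)


@dataclass(frozen=True)
class KMedoidsResult:
    partition: Partition
    medoids: tuple[int, ...]
    objective: float  # mean point-to-own-medoid dissimilarity


def _kmedoids_seed_pp(D: np.ndarray, k: int, rng: np.random.Generator) -> list[int]:
    # k-means++ adapted to a dissimilarity matrix: first medoid uniform,
    # subsequent ones with probability proportional to the squared
    # dissimilarity to the nearest already-chosen medoid.
    n = D.shape[0]
    medoids = [int(rng.integers(n))]
    while len(medoids) < k:
        d2 = D[:, medoids].min(axis=1) ** 2
        d2[medoids] = 0.0
        total = d2.sum()
        if total > 0:
            probs = d2 / total
            medoids.append(int(rng.choice(n, p=probs)))
        else:  # degenerate ties: all remaining points coincide with a medoid
            remaining = [i for i in range(n) if i not in medoids]
            medoids.append(int(rng.choice(remaining)))
    return medoids


def _reseed_empty(D, medoids, assignment, empty_clusters):
    # replace the medoid of each empty cluster by the non-medoid point
    # farthest from its own medoid, so exactly k clusters survive
    for c in empty_clusters:
        non_medoid = np.setdiff1d(np.arange(D.shape[0]), medoids)
        dists = D[non_medoid, np.asarray(medoids)[assignment[non_medoid]]]
        p = int(non_medoid[np.argmax(dists)])
        medoids[c] = p
        assignment[p] = c
    return medoids, assignment


def _kmedoids_single(D: np.ndarray, k: int, rng: np.random.Generator,
                     max_iter: int = 300) -> tuple[np.ndarray, list[int], float]:
    medoids = _kmedoids_seed_pp(D, k, rng)
    assignment = None
    for _ in range(max_iter):
        # assignment: nearest medoid, ties -> lowest medoid list index
        new_assignment = np.argmin(D[:, medoids], axis=1)
        empty = [c for c in range(k) if not np.any(new_assignment == c)]
        if empty:
            medoids, new_assignment = _reseed_empty(D, medoids, new_assignment, empty)
        if assignment is not None and np.array_equal(new_assignment, assignment):
            break
        assignment = new_assignment
        # PAM-style update: each cluster's medoid is its dissimilarity-sum
        # minimizer (exhaustive within the cluster; ties -> lowest node index)
        for c in range(k):
            members = np.flatnonzero(assignment == c)
            within = D[np.ix_(members, members)].sum(axis=1)
            medoids[c] = int(members[np.argmin(within)])
    objective = float(np.mean(D[np.arange(D.shape[0]), np.asarray(medoids)[assignment]]))
    return assignment, medoids, objective


def kmedoids(D: np.ndarray, k: int, n_restarts: int = 20, seed=0) -> KMedoidsResult:
    """k-medoids on a dissimilarity matrix with k-means++ seeding.

    Runs ``n_restarts`` independent restarts (restart r draws from the
    derived stream (seed, r)) and keeps the partition with the lowest mean
    point-to-own-medoid dissimilarity.  Deterministic given ``seed``.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range for {n} points")
    base = _seed_tuple(seed)
    best: tuple[np.ndarray, list[int], float] | None = None
    for r in range(n_restarts):
        rng = np.random.default_rng(base + (r,))
        result = _kmedoids_single(D, k, rng)
        if best is None or result[2] < best[2]:
            best = result
    assignment, medoids, objective = best
    return KMedoidsResult(Partition(assignment), tuple(medoids), objective)


@dataclass(frozen=True)
class SweepResult:
    """Partitions returned by the divisive sweep, keyed by cluster count."""

    partitions: dict[int, Partition]

    @property
    def ks(self) -> list[int]:
        return sorted(self.partitions)

    def __getitem__(self, k: int) -> Partition:
        return self.partitions[k]


def dynamical_communities_sweep(
    net: WeightedNetwork,
    k_max: int | None = None,
    n_restarts: int = 20,
    seed=0,
    inner_iters: int = 1,
) -> SweepResult:
    """Divisive sweep over k = 2..k_max (default N-1).

    Starting from the single-cluster partition, each step computes the
    cluster-degree matrix against the current partition, its dissimilarity
    matrix, and a k-medoids partition with one more cluster, which is
    carried forward.  ``inner_iters`` > 1 repeats the degree/cluster step
    at fixed k until the partition stabilizes (single pass by default).
    """
    n = net.n_nodes
    if n < 3:
        raise ValueError("sweep requires at least 3 nodes")
    if k_max is None:
        k_max = n - 1
    k_max = min(k_max, n - 1)
    base = _seed_tuple(seed)
    current = Partition(np.zeros(n, dtype=int))
    partitions: dict[int, Partition] = {}
    for k in range(2, k_max + 1):
        for it in range(max(1, inner_iters)):
            P = cluster_degree_matrix(net, current)
            D = dissimilarity_matrix(P)
            result = kmedoids(D, k, n_restarts=n_restarts, seed=base + (k, it))
            if result.partition == current:
                break
            current = result.partition
        partitions[k] = current
    return SweepResult(partitions)
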