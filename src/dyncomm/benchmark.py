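"""Comparison of dynamical communities against modularity communities.

The ground truth for "which nodes behave alike" is taken from the
dynamics itself: nodes are clustered (k-means) on their consensus
trajectories sampled over the transient, for every k.  Both the
dynamical-community partitions and a hierarchical modularity-based
community structure are then scored against this trajectory benchmark
with the pair-counting Jaccard index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.cluster import KMeans

from .detect import SweepResult, _seed_tuple, dynamical_communities_sweep
from .dynamics import ConsensusConfig, TrajectorySet, consensus_trajectories, settling_time
from .network import Partition, WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "PartitionSimilarity",
    "jaccard_index",
    "trajectory_benchmark_partition",
    "community_structure_hierarchy",
    "MethodComparison",
    "compare_methods",
]


@dataclass(frozen=True)
class PartitionSimilarity:
    """Pair-counting comparison of two partitions of the same node set.

    n11 counts unordered node pairs co-clustered in both partitions, n10
    pairs co-clustered only in the first, n01 only in the second, n00 in
    neither; jaccard = n11 / (n11 + n10 + n01), defined as 0 when no pair
    is co-clustered in either partition.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    @property
    def jaccard(self) -> float:
        denom = self.n11 + self.n10 + self.n01
        return self.n11 / denom if denom else 0.0


def jaccard_index(p1: Partition, p2: Partition) -> PartitionSimilarity:
    """Pair-counting Jaccard similarity; 1.0 iff the partitions are
    identical up to cluster relabeling.  Symmetric in its arguments."""
    if p1.n_nodes != p2.n_nodes:
        raise ValueError("partitions cover different numbers of nodes")
    a1, a2 = p1.assignment, p2.assignment
    iu = np.triu_indices(p1.n_nodes, k=1)
    same1 = (a1[:, None] == a1[None, :])[iu]
    same2 = (a2[:, None] == a2[None, :])[iu]
    n11 = int(np.sum(same1 & same2))
    n10 = int(np.sum(same1 & ~same2))
    n01 = int(np.sum(~same1 & same2))
    n00 = int(np.sum(~same1 & ~same2))
    return PartitionSimilarity(n11, n10, n01, n00)


def trajectory_benchmark_partition(
    traj: TrajectorySet, k: int, n_restarts: int = 10, seed=0
) -> Partition:
    """k-means on per-node trajectory features (k-means++ seeding,
    ``n_restarts`` restarts, best inertia kept)."""
    n = traj.n_nodes
    if not (2 <= k <= n - 1):
        raise ValueError(f"k={k} out of range 2..{n - 1}")
    rs = int(np.random.SeedSequence(_seed_tuple(seed)).generate_state(1)[0] % (2**31))
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=rs)
    return Partition(km.fit_predict(traj.node_features()))


def community_structure_hierarchy(net: WeightedNetwork) -> dict[int, Partition]:
    """Greedy modularity agglomeration cut at every level k = 2..N-1.

    Directed input is symmetrized as (A + Aᵀ)/2 with a logged warning.
    Merging starts from singletons and is forced to continue past the
    modularity peak so that a partition exists for every k.
    """
    W = net.weights
    if not net.is_symmetric():
        logger.warning("asymmetric adjacency symmetrized as (A + A^T)/2 "
                       "for community detection")
        W = 0.5 * (W + W.T)
    G = nx.from_numpy_array(np.abs(W))
    out: dict[int, Partition] = {}
    for k in range(2, net.n_nodes):
        comms = nx.community.greedy_modularity_communities(
            G, weight="weight", cutoff=k, best_n=k
        )
        out[k] = Partition.from_clusters([sorted(c) for c in comms], net.n_nodes)
    return out


@dataclass(frozen=True)
class MethodComparison:
    """Per-k Jaccard of each method's partition against the trajectory
    benchmark."""

    ks: np.ndarray
    j_dyncomm: np.ndarray
    j_community: np.ndarray


def compare_methods(
    net: WeightedNetwork,
    cfg: ConsensusConfig | None = None,
    k_max: int | None = None,
    n_restarts: int = 20,
    seed=0,
    sweep: SweepResult | None = None,
) -> MethodComparison:
    """Score dynamical communities and community structure against the
    consensus-trajectory benchmark, for every k.

    The benchmark clusters nodes on their consensus trajectories sampled
    at 100 uniform times over [0, settling time].
    """
    from .dynamics import choose_rho  # local to avoid import-cycle noise

    base = _seed_tuple(seed)
    if cfg is None:
        cfg = ConsensusConfig(rho=choose_rho(net))
    if cfg.time_grid is None:
        ts = settling_time(net, cfg)
        cfg = ConsensusConfig(rho=cfg.rho, delta=cfg.delta,
                              time_grid=np.linspace(0.0, ts, 101)[1:])
    traj = consensus_trajectories(net, cfg)
    if sweep is None:
        sweep = dynamical_communities_sweep(net, k_max=k_max,
                                            n_restarts=n_restarts, seed=base + (1,))
    hierarchy = community_structure_hierarchy(net)
    ks = np.array(sweep.ks, dtype=int)
    j_dyn = np.empty(ks.size)
    j_comm = np.empty(ks.size)
    for t, k in enumerate(ks):
        bench = trajectory_benchmark_partition(traj, int(k), seed=base + (2, int(k)))
        j_dyn[t] = jaccard_index(bench, sweep[int(k)]).jaccard
        j_comm[t] = jaccard_index(bench, hierarchy[int(k)]).jaccard
    return MethodComparison(ks=ks, j_dyncomm=j_dyn, j_community=j_comm)
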