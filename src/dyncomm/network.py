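"""Weighted-network container, file I/O, synthetic generation and perturbations.

The adjacency convention throughout the package is *row = receiver*:
``weights[i, j]`` is the weight of the edge from node ``j`` into node ``i``.
Cluster-degree computations, consensus dynamics and oscillator coupling all
inherit this orientation.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedNetwork",
    "Partition",
    "QuotientSpec",
    "read_network",
    "write_network",
    "read_partition",
    "write_partition",
    "random_quotient",
    "planted_equitable_network",
    "perturb",
]


@dataclass(frozen=True)
class WeightedNetwork:
    """A weighted, generically directed network on ``n_nodes`` nodes.

    Parameters
    ----------
    weights
        Real N x N matrix; entry ``(i, j)`` is the weight of the edge from
        node ``j`` into node ``i`` (row = receiver).
    labels
        N unique node identifiers, index-aligned with rows/columns.
    """

    weights: np.ndarray
    labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"adjacency matrix must be square, got shape {W.shape}")
        object.__setattr__(self, "weights", W)
        labels = self.labels
        if labels is None:
            labels = tuple(str(i) for i in range(W.shape[0]))
        else:
            labels = tuple(str(x) for x in labels)
        if len(labels) != W.shape[0]:
            raise ValueError("number of labels must match matrix dimension")
        if len(set(labels)) != len(labels):
            raise ValueError("node labels must be unique")
        object.__setattr__(self, "labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def index_of(self, label: str) -> int:
        return self.labels.index(str(label))

    def is_symmetric(self, tol: float = 1e-12) -> bool:
        return bool(np.allclose(self.weights, self.weights.T, atol=tol, rtol=0.0))

    def permuted(self, perm: np.ndarray) -> "WeightedNetwork":
        """Relabel nodes: new node ``p`` is old node ``perm[p]``."""
        perm = np.asarray(perm)
        return WeightedNetwork(
            self.weights[np.ix_(perm, perm)],
            tuple(self.labels[i] for i in perm),
        )


@dataclass(frozen=True)
class Partition:
    """Assignment of N nodes to ``k`` disjoint non-empty clusters.

    Stored in canonical form: clusters are numbered by order of first
    appearance along the node index, which makes equality of partitions
    directly testable.
    """

    assignment: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        if a.ndim != 1 or a.size == 0:
            raise ValueError("assignment must be a non-empty 1-d sequence")
        # canonicalize: relabel by order of first appearance
        _, first = np.unique(a, return_index=True)
        order = a[np.sort(first)]
        remap = {old: new for new, old in enumerate(order)}
        canon = np.array([remap[x] for x in a], dtype=int)
        object.__setattr__(self, "assignment", canon)

    @property
    def n_nodes(self) -> int:
        return self.assignment.size

    @property
    def k(self) -> int:
        return int(self.assignment.max()) + 1

    def clusters(self) -> list[np.ndarray]:
        """Node indices of each cluster, in cluster order."""
        return [np.flatnonzero(self.assignment == c) for c in range(self.k)]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.k)

    def indicator(self) -> np.ndarray:
        """The N x k binary indicator matrix E (each row sums to 1)."""
        E = np.zeros((self.n_nodes, self.k))
        E[np.arange(self.n_nodes), self.assignment] = 1.0
        return E

    @classmethod
    def from_indicator(cls, E: np.ndarray) -> "Partition":
        E = np.asarray(E)
        if not np.all(E.sum(axis=1) == 1):
            raise ValueError("indicator matrix rows must each sum to 1")
        if not np.all(E.sum(axis=0) >= 1):
            raise ValueError("indicator matrix has an empty cluster column")
        return cls(np.argmax(E, axis=1))

    @classmethod
    def from_clusters(cls, clusters: list[list[int]], n_nodes: int | None = None) -> "Partition":
        n = n_nodes if n_nodes is not None else sum(len(c) for c in clusters)
        a = np.full(n, -1, dtype=int)
        for ci, members in enumerate(clusters):
            a[list(members)] = ci
        if np.any(a < 0):
            raise ValueError("clusters do not cover all nodes")
        return cls(a)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return bool(np.array_equal(self.assignment, other.assignment))

    def __hash__(self) -> int:
        return hash(self.assignment.tobytes())

    def permuted(self, perm: np.ndarray) -> "Partition":
        perm = np.asarray(perm)
        return Partition(self.assignment[perm])


@dataclass(frozen=True)
class QuotientSpec:
    """Recipe for a network with a planted exactly equitable partition.

    ``quotient_weights[u, v]`` is the total weight every node of cluster u
    must receive from cluster v; ``block_density`` is the fraction of
    admissible entries kept nonzero in each block.
    """

    cluster_sizes: tuple[int, ...]
    quotient_weights: np.ndarray
    block_density: float = 1.0

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.cluster_sizes)
        if any(s <= 0 for s in sizes):
            raise ValueError("cluster sizes must be positive")
        object.__setattr__(self, "cluster_sizes", sizes)
        Q = np.asarray(self.quotient_weights, dtype=float)
        k = len(sizes)
        if Q.shape != (k, k):
            raise ValueError(f"quotient matrix must be {k}x{k}, got {Q.shape}")
        object.__setattr__(self, "quotient_weights", Q)
        if not (0.0 < self.block_density <= 1.0):
            raise ValueError("block_density must lie in (0, 1]")

    @property
    def n_nodes(self) -> int:
        return sum(self.cluster_sizes)

    @property
    def k(self) -> int:
        return len(self.cluster_sizes)


# ---------------------------------------------------------------------------
# file I/O

_FORMATS = ("dense", "edgelist", "matrixmarket")


def read_network(path, format: str = "dense", allow_self_loops: bool = False) -> WeightedNetwork:
    """Read a weighted network from ``path``.

    Formats: ``dense`` (whitespace- or comma-separated square matrix),
    ``edgelist`` (TSV with columns source, target, weight; weight optional,
    default 1.0; the entry at (row=target, col=source) receives the weight),
    ``matrixmarket`` (coordinate or array format).
    """
    if format == "dense":
        return _read_dense(path)
    if format == "edgelist":
        return _read_edgelist(path, allow_self_loops=allow_self_loops)
    if format == "matrixmarket":
        M = scipy.io.mmread(path)
        if scipy.sparse.issparse(M):
            M = M.toarray()
        M = np.asarray(M, dtype=float)
        if M.shape[0] != M.shape[1]:
            raise ValueError(f"Matrix Market file is not square: {M.shape}")
        return WeightedNetwork(M)
    raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")


def _read_dense(path) -> WeightedNetwork:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            try:
                rows.append([float(x) for x in parts])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    M = np.array(rows, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{path}: dense matrix is not square (shape {M.shape})")
    return WeightedNetwork(M)


def _read_edgelist(path, allow_self_loops: bool = False) -> WeightedNetwork:
    edges = []
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if line.startswith("# nodes:"):
                for lab in line[len("# nodes:"):].split():
                    labels.setdefault(lab, len(labels))
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ValueError(
                    f"{path}: line {lineno}: expected 'source target [weight]', got {line!r}"
                )
            src, tgt = parts[0], parts[1]
            try:
                w = float(parts[2]) if len(parts) == 3 else 1.0
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: bad weight {parts[2]!r}") from exc
            if src == tgt and not allow_self_loops:
                raise ValueError(f"{path}: line {lineno}: self-loop on node {src!r} rejected")
            for lab in (src, tgt):
                labels.setdefault(lab, len(labels))
            edges.append((src, tgt, w, lineno))
    n = len(labels)
    W = np.zeros((n, n))
    seen: set[tuple[int, int]] = set()
    for src, tgt, w, lineno in edges:
        r, c = labels[tgt], labels[src]  # row = receiver
        if (r, c) in seen:
            logger.warning("%s: line %d: duplicate edge %s->%s accumulated", path, lineno, src, tgt)
        seen.add((r, c))
        W[r, c] += w
    return WeightedNetwork(W, tuple(labels))


def write_network(net: WeightedNetwork, path, format: str = "dense") -> None:
    """Write ``net`` to ``path``; round-trips through :func:`read_network`."""
    if format == "dense":
        np.savetxt(path, net.weights, fmt="%.17g")
    elif format == "edgelist":
        with open(path, "w") as fh:
            fh.write("# nodes: " + " ".join(net.labels) + "\n")
            fh.write("# source\ttarget\tweight\n")
            rows, cols = np.nonzero(net.weights)
            for r, c in zip(rows, cols):
                fh.write(f"{net.labels[c]}\t{net.labels[r]}\t{net.weights[r, c]:.17g}\n")
    elif format == "matrixmarket":
        symmetry = "symmetric" if net.is_symmetric() else "general"
        buf = io.BytesIO()
        scipy.io.mmwrite(
            buf, scipy.sparse.coo_matrix(net.weights), symmetry=symmetry, precision=17
        )
        with open(path, "wb") as fh:
            fh.write(buf.getvalue())
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")


def read_partition(path, net: WeightedNetwork | None = None) -> Partition:
    """Read a two-column TSV (label, cluster index) partition file."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["label", "cluster"],
                     dtype={"label": str, "cluster": int})
    if net is not None:
        order = {lab: i for i, lab in enumerate(net.labels)}
        a = np.full(net.n_nodes, -1, dtype=int)
        for lab, c in zip(df["label"], df["cluster"]):
            if lab not in order:
                raise ValueError(f"{path}: unknown node label {lab!r}")
            a[order[lab]] = c
        if np.any(a < 0):
            raise ValueError(f"{path}: partition does not cover all network nodes")
        return Partition(a)
    return Partition(df["cluster"].to_numpy())


def write_partition(part: Partition, path, labels=None) -> None:
    labels = labels if labels is not None else [str(i) for i in range(part.n_nodes)]
    with open(path, "w") as fh:
        for lab, c in zip(labels, part.assignment):
            fh.write(f"{lab}\t{c}\n")


# ---------------------------------------------------------------------------
# synthetic generation


def random_quotient(
    k: int,
    seed: int | np.random.Generator = 0,
    mean_weight: float = 3.0,
    total_spread: float = 0.6,
) -> np.ndarray:
    """Random k x k quotient matrix with distinct per-cluster totals.

    Entries are positive and uniform; each row u is then rescaled so the
    cluster's total in-strength equals ``mean_weight * k`` scaled by an
    evenly spaced factor in [1 - total_spread/2, 1 + total_spread/2].
    Distinct row totals are the minimal condition for the planted
    partition to be identifiable: if two clusters had identical quotient
    rows they would merge into one equitable cluster, and if their totals
    coincide the clusters are indistinguishable at the coarsest level of
    the divisive hierarchy.
    """
    if k < 1:
        raise ValueError("k must be positive")
    rng = np.random.default_rng(seed)
    Q = rng.uniform(1.0, 5.0, size=(k, k))
    if k == 1:
        return Q
    factors = rng.permutation(np.linspace(1 - total_spread / 2, 1 + total_spread / 2, k))
    targets = mean_weight * k * factors
    return Q * (targets / Q.sum(axis=1))[:, None]


def _balanced_block(
    s_u: int, s_v: int, target: float, density: float, is_diag: bool,
    rng: np.random.Generator, random_weights: bool,
) -> np.ndarray:
    """Random s_u x s_v block with every row summing to ``target`` and
    every column summing to ``target * s_u / s_v``."""
    if s_u == s_v:
        s = s_u
        if s == 1:
            if is_diag:
                raise ValueError(
                    "infeasible spec: a size-1 cluster cannot receive nonzero "
                    "weight from itself without a self-loop"
                )
            return np.array([[target]])
        # combination of distinct cyclic-shift permutations; shift 0 lies
        # on the diagonal and is excluded for diagonal blocks
        shifts_avail = np.arange(1, s) if is_diag else np.arange(s)
        d = max(1, int(round(density * shifts_avail.size)))
        shifts = rng.choice(shifts_avail, size=d, replace=False)
        if random_weights:
            coeffs = rng.uniform(0.5, 1.5, size=d)
            coeffs *= target / coeffs.sum()
        else:
            coeffs = np.full(d, target / d)
        B = np.zeros((s, s))
        idx = np.arange(s)
        for shift, cf in zip(shifts, coeffs):
            B[idx, (idx + shift) % s] += cf
        return B
    # rectangular block: uniform base, optionally plus a double-centered
    # random perturbation (zero row and column sums) keeping entries positive
    base = target / s_v
    if not random_weights:
        return np.full((s_u, s_v), base)
    R = rng.uniform(0.5, 1.5, size=(s_u, s_v))
    X = R - R.mean(axis=1, keepdims=True) - R.mean(axis=0, keepdims=True) + R.mean()
    amax = np.abs(X).max()
    alpha = 0.9 * base / amax if amax > 0 else 0.0
    return base + alpha * X


def planted_equitable_network(
    spec: QuotientSpec, seed: int | np.random.Generator = 0,
    random_weights: bool = False,
) -> tuple[WeightedNetwork, Partition]:
    """Generate a network that is exactly equitable under a planted partition.

    For every node i of cluster u, the total weight received from cluster v
    equals ``spec.quotient_weights[u, v]`` exactly (up to float rounding),
    and symmetrically every node of cluster v sends the same total weight
    into cluster u.  The doubly balanced construction makes the cluster
    subspace invariant under both A and its transpose, so the adjacency
    matrix commutes with the partition's projector and the correction cost
    of the planted partition is zero.  Square blocks are combinations of
    cyclic-shift permutations (``block_density`` controls how many shifts
    are used); rectangular blocks are dense.  Self-loops are never created.

    With the default ``random_weights=False``, all entries of one block
    share one value, so nodes of a cluster have exactly permutation-
    equivalent rows: their coupling sums agree bit for bit in floating
    point, and simulated cluster synchronization persists indefinitely
    instead of being destroyed by chaotic amplification of rounding noise.
    ``random_weights=True`` draws heterogeneous positive weights instead
    (block-row sums still exact; bit-level synchrony is then lost on
    chaotic dynamics).
    """
    rng = np.random.default_rng(seed)
    sizes = spec.cluster_sizes
    Q = spec.quotient_weights
    n = spec.n_nodes
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    assignment = np.concatenate([np.full(s, u) for u, s in enumerate(sizes)])

    W = np.zeros((n, n))
    for u in range(spec.k):
        for v in range(spec.k):
            target = Q[u, v]
            if target == 0.0:
                continue
            B = _balanced_block(sizes[u], sizes[v], target, spec.block_density,
                                is_diag=(u == v), rng=rng,
                                random_weights=random_weights)
            W[offsets[u]:offsets[u + 1], offsets[v]:offsets[v + 1]] = B
    return WeightedNetwork(W), Partition(assignment)


def perturb(
    net: WeightedNetwork,
    epsilon: float,
    kind: str = "type1",
    seed: int | np.random.Generator = 0,
) -> WeightedNetwork:
    """Perturb the adjacency matrix with dense standard-normal noise Q.

    ``type1``: A0 + eps * (Q ∘ A0) — multiplicative on existing edges only,
    so the zero pattern of A0 is preserved exactly.
    ``type2``: A0 + eps * Q — additive noise on every entry.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    rng = np.random.default_rng(seed)
    Qn = rng.standard_normal(net.weights.shape)
    if kind == "type1":
        W = net.weights + epsilon * Qn * net.weights
    elif kind == "type2":
        W = net.weights + epsilon * Qn
    else:
        raise ValueError(f"unknown perturbation kind {kind!r}; expected 'type1' or 'type2'")
    return WeightedNetwork(W, net.labels)
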