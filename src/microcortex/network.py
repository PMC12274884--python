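"""Connectome post-processing and directed-simplex network complexity.

A directed k-simplex is a set of k+1 all-to-all connected nodes whose edges
respect a single linear order (one source, one sink); high-dimensional
simplices flag strongly feed-forward cliques and are the complexity measure
used to compare species networks. Network density follows the n² convention
(edges divided by the squared node count), which is unconventional but kept
for consistency with how the compared quantities are defined.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass
class Connectome:
    """Directed connectivity with per-edge apposition counts.

    ``apposition_counts`` is an (n, n) sparse integer matrix; the boolean
    adjacency is ``apposition_counts > 0``. ``cell_class`` labels nodes
    ('PC'/'IN'); ``cell_ids`` maps node index to the originating circuit
    cell id (identity when standalone).
    """

    apposition_counts: sparse.csr_matrix
    cell_class: np.ndarray
    cell_ids: np.ndarray | None = None

    def __post_init__(self):
        self.apposition_counts = sparse.csr_matrix(self.apposition_counts)
        n = self.apposition_counts.shape[0]
        if self.apposition_counts.shape[1] != n:
            raise ValueError("adjacency must be square")
        self.cell_class = np.asarray(self.cell_class)
        if len(self.cell_class) != n:
            raise ValueError("cell_class length mismatch")
        if self.cell_ids is None:
            self.cell_ids = np.arange(n)
        if self.apposition_counts.diagonal().any():
            raise ValueError("self-edges are not allowed")

    @property
    def n_cells(self) -> int:
        return self.apposition_counts.shape[0]

    @property
    def n_edges(self) -> int:
        return int((self.apposition_counts > 0).sum())

    @property
    def density(self) -> float:
        """Edges over squared node count (n² convention)."""
        return self.n_edges / self.n_cells**2

    def adjacency(self) -> sparse.csr_matrix:
        return (self.apposition_counts > 0).astype(np.int8).tocsr()

    def edge_list(self) -> pd.DataFrame:
        coo = self.apposition_counts.tocoo()
        return pd.DataFrame(
            {"src": coo.row, "dst": coo.col, "appositions": coo.data}
        ).sort_values(["src", "dst"], ignore_index=True)

    def subset(self, nodes) -> "Connectome":
        nodes = np.asarray(nodes)
        sub = self.apposition_counts[nodes][:, nodes]
        return Connectome(sub, self.cell_class[nodes], self.cell_ids[nodes])

    def class_subset(self, cls: str) -> "Connectome":
        return self.subset(np.flatnonzero(self.cell_class == cls))


def connectome_from_edges(n, edges, cell_class=None, counts=None) -> Connectome:
    """Build a Connectome from an iterable of (src, dst) pairs."""
    edges = np.asarray(list(edges), dtype=np.int64).reshape(-1, 2)
    data = np.ones(len(edges), dtype=np.int64) if counts is None else np.asarray(counts)
    mat = sparse.csr_matrix(
        (data, (edges[:, 0], edges[:, 1])), shape=(n, n), dtype=np.int64
    )
    if cell_class is None:
        cell_class = np.array(["PC"] * n)
    return Connectome(mat, cell_class)


# ---------------------------------------------------------------------------
# Pruning and density statistics


def prune_to_density(conn: Connectome, target_density: float = 0.04, seed: int = 0) -> Connectome:
    """Keep a uniformly random subset of floor(target · n²) edges.

    Random apposition selection down to a biologically plausible ~4%
    connection density; apposition counts of kept edges are preserved."""
    n = conn.n_cells
    target_edges = int(np.floor(target_density * n * n))
    coo = conn.apposition_counts.tocoo()
    current = len(coo.data)
    if current < target_edges:
        raise ValueError(
            f"current density {current / n**2:.4f} below target {target_density:.4f}"
        )
    rng = np.random.default_rng(seed)
    keep = rng.choice(current, size=target_edges, replace=False)
    mat = sparse.csr_matrix(
        (coo.data[keep], (coo.row[keep], coo.col[keep])), shape=(n, n)
    )
    return Connectome(mat, conn.cell_class.copy(), conn.cell_ids.copy())


def expected_connection_probability(
    synapses_per_neuron: float, synapses_per_connection: float, n_cells: int
) -> float:
    """Connection probability implied by per-neuron synapse statistics.

    The mean in-degree is s/c (synapses per neuron over synapses per
    connection); over n cells the probability is n·(s/c) / (n² − n)."""
    if synapses_per_connection <= 0:
        raise ValueError("synapses_per_connection must be positive")
    if synapses_per_neuron <= 0 or n_cells < 2:
        raise ValueError("need positive synapse count and n_cells >= 2")
    in_degree = synapses_per_neuron / synapses_per_connection
    return n_cells * in_degree / (n_cells**2 - n_cells)


def subnetwork_density(conn: Connectome, node_subset) -> float:
    """Edges within the subset over the squared subset size."""
    node_subset = np.asarray(node_subset)
    if len(node_subset) == 0:
        raise ValueError("empty node subset")
    sub = conn.adjacency()[node_subset][:, node_subset]
    return float(sub.sum() / len(node_subset) ** 2)


def in_degree_distribution(conn: Connectome, node_subset=None) -> np.ndarray:
    """In-degrees computed within the subset (all nodes by default)."""
    if node_subset is None:
        node_subset = np.arange(conn.n_cells)
    node_subset = np.asarray(node_subset)
    if len(node_subset) == 0:
        raise ValueError("empty node subset")
    sub = conn.adjacency()[node_subset][:, node_subset]
    return np.asarray(sub.sum(axis=0)).ravel()


# ---------------------------------------------------------------------------
# Directed simplex counting


@dataclass
class SimplexCounts:
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def max_dimension(self) -> int:
        nz = np.flatnonzero(self.counts)
        return int(nz[-1]) if len(nz) else 0

    def to_dict(self) -> dict:
        return {int(k): int(v) for k, v in enumerate(self.counts)}


def count_directed_simplices(conn: Connectome, max_dim: int | None = None) -> SimplexCounts:
    """Exact directed simplex counts per dimension.

    counts[k] = number of (k+1)-tuples of distinct nodes (v0, ..., vk) with
    an edge vi→vj for every i < j. Enumerates by successively intersecting
    out-neighborhoods, so each directed clique is counted once per linear
    extension consistent with its edge directions (reciprocal edges simply
    yield several valid orderings; nothing is collapsed)."""
    adj = conn.adjacency()
    n = conn.n_cells
    out_sets = [set(adj.indices[adj.indptr[i] : adj.indptr[i + 1]].tolist()) - {i} for i in range(n)]
    counts = [n]

    def extend(candidates: set, dim: int):
        while len(counts) <= dim:
            counts.append(0)
        counts[dim] += len(candidates)
        if max_dim is not None and dim >= max_dim:
            return
        for v in candidates:
            deeper = candidates & out_sets[v]
            if deeper:
                extend(deeper, dim + 1)

    for v0 in range(n):
        if out_sets[v0]:
            extend(out_sets[v0], 1)
    if len(counts) == 1:
        counts.append(0)
    return SimplexCounts(np.array(counts))


def simplex_profile_distance(a: SimplexCounts, b: SimplexCounts) -> float:
    """L1 distance between normalized simplex-count distributions over
    dimensions (profiles padded to a common length)."""
    la, lb = len(a.counts), len(b.counts)
    size = max(la, lb)
    pa = np.zeros(size)
    pb = np.zeros(size)
    pa[:la] = a.counts
    pb[:lb] = b.counts
    if pa.sum() > 0:
        pa = pa / pa.sum()
    if pb.sum() > 0:
        pb = pb / pb.sum()
    return float(np.abs(pa - pb).sum())


# ---------------------------------------------------------------------------
# Null models


def erdos_renyi_directed(n: int, density: float, seed: int = 0) -> Connectome:
    """Directed Erdős–Rényi graph: each ordered pair (i≠j) is an edge with
    probability ``density`` (n² convention at large n)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 <= density <= 1:
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mat = rng.random((n, n)) < density
    np.fill_diagonal(mat, False)
    return Connectome(
        sparse.csr_matrix(mat.astype(np.int64)), np.array(["PC"] * n)
    )


def watts_strogatz_directed(n: int, k: int, p: float, seed: int = 0) -> Connectome:
    """Directed small-world graph.

    Starts from a directed ring lattice in which every node sends an edge to
    its k nearest neighbors (k/2 on each side), then rewires each edge's
    target uniformly at random with probability ``p`` (avoiding self-loops
    and duplicate edges). At p=0 every out-degree equals k exactly."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if k % 2 != 0 or k <= 0 or k >= n:
        raise ValueError("k must be even, positive and < n")
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    targets = [set() for _ in range(n)]
    for i in range(n):
        for d in range(1, k // 2 + 1):
            targets[i].add((i + d) % n)
            targets[i].add((i - d) % n)
    for i in range(n):
        for j in sorted(targets[i]):
            if rng.random() < p:
                choices = [
                    t for t in range(n) if t != i and t not in targets[i]
                ]
                if choices:
                    targets[i].remove(j)
                    targets[i].add(choices[int(rng.integers(len(choices)))])
    edges = [(i, j) for i in range(n) for j in sorted(targets[i])]
    return connectome_from_edges(n, edges)
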