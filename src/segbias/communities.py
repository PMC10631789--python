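"""Subject-specific community detection and modularity.

Modularity under the configuration null:

    Q = (1/2m) sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j)

with A the (weighted) adjacency, k the weighted degrees and 2m the total
weight.  A general null model can be supplied as an explicit expected-weight
matrix.  Louvain and Girvan-Newman partitions feed back into the system
segregation measure as subject-specific parcellations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectivity import ConnectivityMatrix
from .segregation import Parcellation, SegregationResult, system_segregation

__all__ = [
    "Partition",
    "modularity",
    "louvain",
    "girvan_newman",
    "subject_specific_segregation",
]


@dataclass
class Partition:
    """Node-to-community assignment with its modularity value."""

    assignment: np.ndarray  # int community id per node, contiguous from 0
    q: float

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        ids = np.unique(a)
        if not np.array_equal(ids, np.arange(ids.size)):
            raise ValueError("community ids must be contiguous from 0")
        self.assignment = a

    @property
    def n_communities(self) -> int:
        return int(self.assignment.max()) + 1


def _canonical_labels(assignment: np.ndarray) -> np.ndarray:
    """Relabel communities 0.. in order of first appearance."""
    out = np.empty_like(assignment)
    seen: dict[int, int] = {}
    for i, c in enumerate(assignment):
        if c not in seen:
            seen[c] = len(seen)
        out[i] = seen[c]
    return out


def modularity(
    cm: ConnectivityMatrix | np.ndarray,
    assignment: np.ndarray,
    expected: np.ndarray | None = None,
) -> float:
    """Modularity Q of a partition; configuration null unless ``expected`` given."""
    a = cm.values if isinstance(cm, ConnectivityMatrix) else np.asarray(cm, float)
    c = np.asarray(assignment, dtype=int)
    if c.shape[0] != a.shape[0]:
        raise ValueError("assignment length must match matrix size")
    two_m = a.sum()
    if two_m <= 0:
        raise ValueError("empty graph: total weight is 0")
    if expected is None:
        k = a.sum(axis=1)
        expected = np.outer(k, k) / two_m
    delta = c[:, None] == c[None, :]
    return float(((a - expected) * delta).sum() / two_m)


def _partition_from_sets(n: int, communities) -> np.ndarray:
    assignment = np.empty(n, dtype=int)
    # stable ordering: communities sorted by their smallest node
    for cid, nodes in enumerate(sorted(map(sorted, communities))):
        assignment[list(nodes)] = cid
    return _canonical_labels(assignment)


def _to_graph(cm: ConnectivityMatrix) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(cm.n_nodes))
    iu, ju = np.nonzero(np.triu(cm.values, k=1))
    for i, j in zip(iu.tolist(), ju.tolist()):
        w = cm.values[i, j]
        g.add_edge(i, j, weight=w, distance=1.0 / w)
    return g


def louvain(cm: ConnectivityMatrix, seed: int = 0, n_runs: int = 20) -> Partition:
    """Best-of-``n_runs`` Louvain partition at resolution 1.

    Each run randomizes the node sweep order from a seeded stream; the
    returned ``q`` is recomputed exactly from the partition.
    """
    if cm.values.sum() <= 0:
        raise ValueError("empty graph: total weight is 0")
    g = _to_graph(cm)
    rng = np.random.default_rng(seed)
    best: Partition | None = None
    for _ in range(max(1, n_runs)):
        run_seed = int(rng.integers(0, 2**31 - 1))
        comms = nx.community.louvain_communities(
            g, weight="weight", resolution=1.0, seed=run_seed
        )
        assignment = _partition_from_sets(cm.n_nodes, comms)
        q = modularity(cm, assignment)
        if best is None or q > best.q:
            best = Partition(assignment, q)
    return best


def girvan_newman(cm: ConnectivityMatrix) -> Partition:
    """Divisive Girvan-Newman clustering, keeping the max-modularity cut.

    Edges are removed in order of highest betweenness (recomputed after each
    removal, with edge length 1/weight for shortest paths; ties broken by
    ascending edge index).  Among the component partitions produced along
    the way, the one maximizing configuration-null modularity is returned.
    """
    if cm.values.sum() <= 0:
        raise ValueError("empty graph: total weight is 0")
    g = _to_graph(cm)
    best_assignment = _partition_from_sets(cm.n_nodes, nx.connected_components(g))
    best_q = modularity(cm, best_assignment)
    while g.number_of_edges() > 0:
        ebc = nx.edge_betweenness_centrality(g, weight="distance")
        target = max(ebc.items(), key=lambda kv: (kv[1], [-kv[0][0], -kv[0][1]]))[0]
        g.remove_edge(*target)
        assignment = _partition_from_sets(cm.n_nodes, nx.connected_components(g))
        q = modularity(cm, assignment)
        if q > best_q:
            best_q, best_assignment = q, assignment
    return Partition(best_assignment, best_q)


def _merge_small_modules(cm: ConnectivityMatrix, assignment: np.ndarray) -> np.ndarray:
    """Fold modules of < 2 nodes into the neighbour module with max connectivity."""
    a = assignment.copy()
    while True:
        ids, counts = np.unique(a, return_counts=True)
        small = ids[counts < 2]
        if small.size == 0 or ids.size <= 1:
            break
        sid = small[0]
        nodes = np.flatnonzero(a == sid)
        strengths = {
            other: cm.values[np.ix_(nodes, np.flatnonzero(a == other))].sum()
            for other in ids
            if other != sid
        }
        target = max(strengths, key=lambda o: (strengths[o], -o))
        warnings.warn(f"module {sid} has < 2 nodes; merged into module {target}")
        a[nodes] = target
    return _canonical_labels(a)


def subject_specific_segregation(
    cm: ConnectivityMatrix, part: Partition
) -> SegregationResult:
    """System segregation using a subject's detected modules as the parcellation.

    Modules with fewer than 2 nodes are merged into their most strongly
    connected neighbour module first.  If fewer than 2 modules remain, the
    result is undefined (NaN) with a warning.
    """
    assignment = _merge_small_modules(cm, part.assignment)
    if np.unique(assignment).size < 2:
        warnings.warn("fewer than 2 modules detected; segregation undefined")
        return SegregationResult("whole_brain", np.nan, np.nan, np.nan)
    parc = Parcellation("subject_modules", [f"m{c}" for c in assignment])
    whole, _ = system_segregation(cm, parc)
    return whole
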