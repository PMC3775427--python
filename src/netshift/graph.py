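"""Binary graph construction and metrics at matched sparsity.

Weighted matrices are binarized by keeping the top-weighted node pairs so
that both networks have exactly the same edge count at each sparsity level
(the matched-sparsity contract).  The metrics of interest on the resulting
binary undirected graphs — global efficiency, mean clustering coefficient
and Newman's modularity Q with Louvain partitioning — are implemented
here directly, together with random-network references.

Conventions (chosen once, so edge counts and metric values are bit-stable):

* edge count m = round-half-away-from-zero of s·n(n−1)/2;
* weight ties at the threshold boundary break by (i, j) index order;
* Q on disconnected graphs is computed on the full graph from the formula;
* Q is evaluated with an exact integer numerator (adjacency, degrees and m
  are integers) and one final division, so it is reproducible to the bit.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from ._seeds import as_seed_sequence
from .matrices import ConnectivityMatrix

__all__ = [
    "BinaryGraph",
    "Partition",
    "RandomReference",
    "threshold_sparsity",
    "degree",
    "global_efficiency",
    "clustering",
    "modularity_q",
    "louvain",
    "random_reference",
    "maslov_sneppen",
    "sparsity_sweep",
    "sparsity_grid",
]


class BinaryGraph:
    """Undirected unweighted simple graph with labeled nodes.

    Edges are stored as a sorted array of pair codes ``i * n + j`` with
    ``i < j``; two graphs are equal iff they share node count and edge set.
    """

    __slots__ = ("n_nodes", "edge_ids", "labels", "_adj")

    def __init__(self, n_nodes: int, edge_ids, labels=None):
        self.n_nodes = int(n_nodes)
        ids = np.unique(np.asarray(edge_ids, dtype=np.int64))
        if ids.size:
            i, j = np.divmod(ids, self.n_nodes)
            if ids.min() < 0 or ids.max() >= self.n_nodes * self.n_nodes or np.any(i >= j):
                raise ValueError("edge codes must encode pairs i < j within the node range")
        self.edge_ids = ids
        self.labels = (
            [str(x) for x in labels]
            if labels is not None
            else [f"n{i}" for i in range(self.n_nodes)]
        )
        if len(self.labels) != self.n_nodes:
            raise ValueError("one label per node required")
        self._adj = None

    @classmethod
    def from_edges(cls, n_nodes: int, pairs: Iterable[tuple[int, int]], labels=None):
        codes = []
        for a, b in pairs:
            if a == b:
                raise ValueError("self-loops are not allowed")
            i, j = (a, b) if a < b else (b, a)
            codes.append(i * n_nodes + j)
        return cls(n_nodes, codes, labels)

    @property
    def n_edges(self) -> int:
        return int(self.edge_ids.size)

    @property
    def n_pairs(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    @property
    def sparsity(self) -> float:
        return self.n_edges / self.n_pairs

    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(i, j) endpoint arrays with i < j."""
        return np.divmod(self.edge_ids, self.n_nodes)

    @property
    def edges(self) -> set[tuple[int, int]]:
        i, j = self.pairs()
        return set(zip(i.tolist(), j.tolist()))

    def adjacency(self) -> np.ndarray:
        """Boolean adjacency matrix (cached)."""
        if self._adj is None:
            a = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
            i, j = self.pairs()
            a[i, j] = a[j, i] = True
            self._adj = a
        return self._adj

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BinaryGraph)
            and self.n_nodes == other.n_nodes
            and np.array_equal(self.edge_ids, other.edge_ids)
        )

    def __hash__(self):  # pragma: no cover - graphs are not dict keys in the pipeline
        return hash((self.n_nodes, self.edge_ids.tobytes()))

    def __repr__(self) -> str:
        return f"BinaryGraph(n={self.n_nodes}, m={self.n_edges}, sparsity={self.sparsity:.3f})"


@dataclass
class Partition:
    """A module assignment (contiguous ids from 0) and its modularity Q."""

    assignment: np.ndarray
    q: float

    def __post_init__(self) -> None:
        self.assignment = _renumber(np.asarray(self.assignment, dtype=np.int64))

    @property
    def n_modules(self) -> int:
        return int(self.assignment.max()) + 1 if self.assignment.size else 0


def _renumber(assignment: np.ndarray) -> np.ndarray:
    """Relabel module ids contiguously from 0 in first-appearance order."""
    _, idx, inv = np.unique(assignment, return_index=True, return_inverse=True)
    order = np.argsort(np.argsort(idx))
    return order[inv]


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def threshold_sparsity(w: ConnectivityMatrix, s: float) -> BinaryGraph:
    """Keep the top m = round(s·n(n−1)/2) weighted pairs as binary edges.

    Every retained weight is >= every dropped weight; exact weight ties at
    the boundary break deterministically by (i, j) index order.  The
    diagonal is ignored.  m = 0 and m = all pairs are rejected.
    """
    if not 0 < s < 1:
        raise ValueError("sparsity must lie strictly between 0 and 1")
    n = w.n_nodes
    n_pairs = n * (n - 1) // 2
    m = _round_half_away(s * n_pairs)
    if m <= 0 or m >= n_pairs:
        raise ValueError(
            f"sparsity {s} keeps {m} of {n_pairs} pairs; need an intermediate count"
        )
    iu, ju = np.triu_indices(n, k=1)
    weights = w.values[iu, ju]
    order = np.lexsort((ju, iu, -weights))  # primary: weight desc; ties: (i, j)
    keep = order[:m]
    return BinaryGraph(n, iu[keep].astype(np.int64) * n + ju[keep], labels=w.labels)


def degree(g: BinaryGraph) -> np.ndarray:
    """Number of edges incident to each node."""
    i, j = g.pairs()
    return np.bincount(np.concatenate([i, j]), minlength=g.n_nodes)


def _distance_matrix(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths by simultaneous BFS."""
    n = adj.shape[0]
    a = adj.astype(np.float64)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    frontier = adj.copy()
    reached = adj | np.eye(n, dtype=bool)
    d = 1
    while frontier.any():
        dist[frontier] = d
        nxt = ((frontier @ a) > 0) & ~reached
        reached |= nxt
        frontier = nxt
        d += 1
    return dist


def global_efficiency(g: BinaryGraph) -> float:
    """Mean of 1/d(i, j) over ordered pairs i ≠ j (0 for unreachable pairs)."""
    n = g.n_nodes
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    dist = _distance_matrix(g.adjacency())
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0  # diagonal zeros and disconnected pairs
    return float(inv.sum() / (n * (n - 1)))


@dataclass
class ClusteringResult:
    per_node: np.ndarray
    mean: float


def clustering(g: BinaryGraph) -> ClusteringResult:
    """Per-node clustering coefficient C_i = 2·t_i / (k_i(k_i−1)) and its mean.

    t_i counts triangles through node i; nodes with degree < 2 get C_i = 0.
    """
    a = g.adjacency().astype(np.int64)
    k = degree(g)
    triangles = np.diag(a @ a @ a) // 2
    c = np.zeros(g.n_nodes)
    ok = k >= 2
    c[ok] = 2.0 * triangles[ok] / (k[ok] * (k[ok] - 1))
    return ClusteringResult(c, float(c.mean()))


def modularity_q(g: BinaryGraph, partition) -> float:
    """Newman's Q for a module assignment on a binary graph.

    Q = (1/2m) Σ_ij [A_ij − k_i k_j / 2m] δ(c_i, c_j) over ordered pairs
    (diagonal included).  Evaluated as an exact integer numerator over
    (2m)², then divided once.
    """
    if g.n_edges == 0:
        raise ValueError("modularity is undefined for an empty graph")
    assignment = partition.assignment if isinstance(partition, Partition) else np.asarray(partition)
    if assignment.shape != (g.n_nodes,):
        raise ValueError("partition must assign a module to every node")
    a = g.adjacency().astype(np.int64)
    k = degree(g).astype(object)  # exact integer arithmetic, no overflow
    m2 = 2 * g.n_edges
    numer = 0
    for c in np.unique(assignment):
        idx = np.flatnonzero(assignment == c)
        a_in = int(a[np.ix_(idx, idx)].sum())  # ordered pairs within the module
        k_c = int(sum(k[idx]))
        numer += m2 * a_in - k_c * k_c
    return float(numer / (m2 * m2))


# ---------------------------------------------------------------------------
# Louvain (greedy modularity optimization: local moves + aggregation)

def _one_level(neighbors, k, m2, order, comm, sum_tot):
    """One pass of local node moves; mutates comm/sum_tot, returns whether any node moved."""
    improved = False
    moved = True
    while moved:
        moved = False
        for i in order:
            c0 = comm[i]
            ki = k[i]
            sum_tot[c0] -= ki
            links = {}
            for j, w in neighbors[i].items():
                cj = comm[j]
                links[cj] = links.get(cj, 0.0) + w
            best_c = c0
            best_gain = links.get(c0, 0.0) - sum_tot[c0] * ki / m2
            for c, wv in links.items():
                if c == c0:
                    continue
                gain = wv - sum_tot[c] * ki / m2
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
            comm[i] = best_c
            sum_tot[best_c] += ki
            if best_c != c0:
                moved = improved = True
    return improved


def _louvain_run(g: BinaryGraph, rng: np.random.Generator) -> np.ndarray:
    n = g.n_nodes
    i_arr, j_arr = g.pairs()
    neighbors = [dict() for _ in range(n)]
    for a, b in zip(i_arr.tolist(), j_arr.tolist()):
        neighbors[a][b] = neighbors[a].get(b, 0.0) + 1.0
        neighbors[b][a] = neighbors[b].get(a, 0.0) + 1.0
    k = [float(sum(d.values())) for d in neighbors]
    m2 = 2.0 * g.n_edges
    assign = np.arange(n)  # original node -> current-level community
    while True:
        n_cur = len(neighbors)
        comm = list(range(n_cur))
        sum_tot = k.copy()
        order = rng.permutation(n_cur)
        improved = _one_level(neighbors, k, m2, order, comm, sum_tot)
        comm = _renumber(np.asarray(comm))
        assign = comm[assign]
        n_new = int(comm.max()) + 1
        if not improved or n_new == n_cur:
            break
        # aggregate: communities become nodes; between-community weights sum
        new_neighbors = [dict() for _ in range(n_new)]
        new_k = [0.0] * n_new
        for u in range(n_cur):
            cu = comm[u]
            new_k[cu] += k[u]
            for v, w in neighbors[u].items():
                cv = comm[v]
                if cu != cv:
                    new_neighbors[cu][cv] = new_neighbors[cu].get(cv, 0.0) + w
        neighbors, k = new_neighbors, new_k
    return assign


def louvain(g: BinaryGraph, seed=0, restarts: int = 10) -> Partition:
    """Best-of-``restarts`` greedy modularity partition.

    Node-move order is shuffled per restart from ``seed``; the returned
    ``q`` is recomputed exactly with :func:`modularity_q`, and the highest-Q
    restart wins (first winner kept on ties).
    """
    if g.n_edges == 0:
        raise ValueError("Louvain requires at least one edge")
    if restarts < 1:
        raise ValueError("need at least one restart")
    rng = np.random.default_rng(as_seed_sequence(seed))
    best: Partition | None = None
    for _ in range(restarts):
        assign = _louvain_run(g, rng)
        q = modularity_q(g, assign)
        if best is None or q > best.q:
            best = Partition(assign, q)
    return best


# ---------------------------------------------------------------------------
# Random references

@dataclass
class RandomReference:
    """Metric means over random reference graphs."""

    efficiency: float
    clustering: float
    modularity: float
    reps: int


def _gnm_edges(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    iu, ju = np.triu_indices(n, k=1)
    codes = iu.astype(np.int64) * n + ju
    return rng.choice(codes, size=m, replace=False)


def random_reference(
    n: int,
    m: int,
    reps: int = 1000,
    seed=0,
    louvain_restarts: int = 1,
) -> RandomReference:
    """Mean efficiency / clustering / Q over uniform G(n, m) graphs.

    The reference random networks match the observed graphs in node and
    edge count only; degree-preserving references are available through
    :func:`maslov_sneppen`.
    """
    n_pairs = n * (n - 1) // 2
    if not 0 < m <= n_pairs:
        raise ValueError(f"cannot place {m} edges on {n_pairs} pairs")
    root = as_seed_sequence(seed)
    eff = np.empty(reps)
    clu = np.empty(reps)
    q = np.empty(reps)
    for r, child in enumerate(root.spawn(reps)):
        rng = np.random.default_rng(child)
        g = BinaryGraph(n, _gnm_edges(n, m, rng))
        eff[r] = global_efficiency(g)
        clu[r] = clustering(g).mean
        q[r] = louvain(g, seed=child.spawn(1)[0], restarts=louvain_restarts).q
    return RandomReference(float(eff.mean()), float(clu.mean()), float(q.mean()), reps)


def maslov_sneppen(g: BinaryGraph, swaps_per_edge: int = 10, seed=0) -> BinaryGraph:
    """Degree-preserving rewiring by repeated double-edge swaps."""
    rng = np.random.default_rng(as_seed_sequence(seed))
    n = g.n_nodes
    edges = list(zip(*g.pairs()))
    edge_set = set(g.edge_ids.tolist())
    m = len(edges)
    attempts = swaps_per_edge * m
    for _ in range(attempts):
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            p, q_ = (a, d), (c, b)
        else:
            p, q_ = (a, c), (b, d)
        (p, q_) = (tuple(sorted(p)), tuple(sorted(q_)))
        if p[0] == p[1] or q_[0] == q_[1]:
            continue
        pc, qc = p[0] * n + p[1], q_[0] * n + q_[1]
        if pc in edge_set or qc in edge_set or pc == qc:
            continue
        edge_set.discard(a * n + b)
        edge_set.discard(c * n + d)
        edge_set.add(pc)
        edge_set.add(qc)
        edges[e1], edges[e2] = p, q_
    return BinaryGraph(n, sorted(edge_set), labels=g.labels)


# ---------------------------------------------------------------------------
# Sparsity sweep

METRIC_NAMES = ("efficiency", "clustering", "modularity")
_ALIASES = {"eff": "efficiency", "clust": "clustering", "q": "modularity"}


def canonical_metric(name: str) -> str:
    name = name.lower()
    name = _ALIASES.get(name, name)
    if name not in METRIC_NAMES:
        raise ValueError(f"unknown metric {name!r}; choose from {METRIC_NAMES}")
    return name


def metric_value(g: BinaryGraph, metric: str, seed=0, louvain_restarts: int = 10) -> float:
    """Evaluate one named metric on a binary graph."""
    metric = canonical_metric(metric)
    if metric == "efficiency":
        return global_efficiency(g)
    if metric == "clustering":
        return clustering(g).mean
    return louvain(g, seed=seed, restarts=louvain_restarts).q


def sparsity_grid(low: float = 0.06, high: float = 0.40, step: float = 0.01) -> np.ndarray:
    """The sweep grid (default 6–40% in 1% steps → 35 levels)."""
    n_steps = int(round((high - low) / step))
    grid = low + step * np.arange(n_steps + 1)
    return np.round(grid, 10)


def sparsity_sweep(
    w: ConnectivityMatrix,
    metrics=METRIC_NAMES,
    grid=None,
    network: str = "observed",
    random_reps: int = 0,
    seed=0,
    louvain_restarts: int = 10,
) -> pd.DataFrame:
    """Metric values per sparsity, tidy: (metric, network, sparsity, value).

    With ``random_reps > 0``, mean values over G(n, m) references are
    appended under network name ``"random"``.
    """
    grid = sparsity_grid() if grid is None else np.asarray(grid, dtype=float)
    metrics = [canonical_metric(m) for m in metrics]
    root = as_seed_sequence(seed)
    rows = []
    for idx, s in enumerate(grid):
        g = threshold_sparsity(w, float(s))
        child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(idx,))
        for metric in metrics:
            rows.append((metric, network, float(s), metric_value(g, metric, seed=child, louvain_restarts=louvain_restarts)))
        if random_reps > 0:
            ref = random_reference(g.n_nodes, g.n_edges, reps=random_reps, seed=child.spawn(1)[0])
            for metric in metrics:
                rows.append((metric, "random", float(s), getattr(ref, metric)))
    return pd.DataFrame(rows, columns=["metric", "network", "sparsity", "value"])
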