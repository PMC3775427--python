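"""Binary graph metrics against closed forms, brute force, and networkx."""
import itertools

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import netshift as ns
from netshift.graph import (
    BinaryGraph,
    maslov_sneppen,
    metric_value,
    sparsity_grid,
)
from conftest import random_graph, random_symmetric


def path_graph(k):
    return BinaryGraph.from_edges(k, [(i, i + 1) for i in range(k - 1)])


def complete_graph(k):
    return BinaryGraph.from_edges(k, itertools.combinations(range(k), 2))


# --- independent oracles -----------------------------------------------------

def floyd_warshall(g):
    n = g.n_nodes
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0)
    for i, j in g.edges:
        d[i, j] = d[j, i] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_efficiency(g):
    d = floyd_warshall(g)
    n = g.n_nodes
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def brute_clustering(g):
    a = g.adjacency()
    n = g.n_nodes
    c = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = nbrs.size
        if k < 2:
            continue
        links = sum(1 for u, v in itertools.combinations(nbrs, 2) if a[u, v])
        c[i] = 2.0 * links / (k * (k - 1))
    return c


def brute_modularity(g, assignment):
    a = g.adjacency().astype(int)
    k = a.sum(axis=1)
    m2 = 2 * g.n_edges
    total = 0.0
    for i in range(g.n_nodes):
        for j in range(g.n_nodes):
            if assignment[i] == assignment[j]:
                total += a[i, j] - k[i] * k[j] / m2
    return total / m2


# --- thresholding ------------------------------------------------------------

class TestThreshold:
    def test_study_scale_edge_count(self, rng):
        w = random_symmetric(140, rng)
        g = ns.threshold_sparsity(w, 0.20)
        assert g.n_edges == 1946  # round(0.20 * 9730)
        assert g.sparsity == 1946 / 9730

    def test_top_ranked_pairs_survive(self):
        w = np.array([
            [0, 6, 5, 4],
            [6, 0, 3, 2],
            [5, 3, 0, 1],
            [4, 2, 1, 0],
        ], dtype=float)
        g = ns.threshold_sparsity(ns.ConnectivityMatrix(w, list("abcd")), 0.5)
        assert g.edges == {(0, 1), (0, 2), (0, 3)}  # weights 6, 5, 4

    def test_retained_weights_dominate_dropped(self, rng):
        w = random_symmetric(30, rng)
        g = ns.threshold_sparsity(w, 0.3)
        iu = np.triu_indices(30, k=1)
        kept = np.zeros(iu[0].size, dtype=bool)
        codes = iu[0] * 30 + iu[1]
        kept[np.isin(codes, g.edge_ids)] = True
        vals = w.values[iu]
        assert vals[kept].min() >= vals[~kept].max()

    def test_matched_sparsity_contract(self, rng):
        """Different matrices, same s -> exactly equal edge counts."""
        for s in (0.06, 0.17, 0.40):
            g1 = ns.threshold_sparsity(random_symmetric(50, rng), s)
            g2 = ns.threshold_sparsity(random_symmetric(50, rng), s)
            assert g1.n_edges == g2.n_edges

    def test_weight_ties_break_deterministically(self):
        w = np.ones((5, 5))
        m = ns.ConnectivityMatrix(w, list("abcde"))
        g = ns.threshold_sparsity(m, 0.3)  # 3 of 10 all-tied pairs
        assert g.edges == {(0, 1), (0, 2), (0, 3)}  # lexicographic (i, j)

    def test_degenerate_sparsity_rejected(self, rng):
        w = random_symmetric(10, rng)
        for s in (0.001, 0.999):
            with pytest.raises(ValueError):
                ns.threshold_sparsity(w, s)


# --- closed forms ------------------------------------------------------------

class TestClosedForms:
    def test_complete_graph_efficiency_is_one(self):
        assert ns.global_efficiency(complete_graph(6)) == 1.0

    def test_empty_graph_efficiency_is_zero(self):
        assert ns.global_efficiency(BinaryGraph(5, [])) == 0.0

    def test_three_node_path_efficiency(self):
        assert ns.global_efficiency(path_graph(3)) == 5.0 / 6.0

    def test_triangle_clustering_is_one(self):
        res = ns.clustering(complete_graph(3))
        np.testing.assert_array_equal(res.per_node, np.ones(3))
        assert res.mean == 1.0

    def test_four_cycle_clustering_is_zero(self):
        g = BinaryGraph.from_edges(4, [(0, 1), (1, 2), (2, 3), (0, 3)])
        assert ns.clustering(g).mean == 0.0

    def test_single_module_q_is_zero(self, rng):
        g = random_graph(12, 0.4, rng)
        assert ns.modularity_q(g, np.zeros(12, dtype=int)) == 0.0

    def test_two_disconnected_triangles_q_half(self):
        g = BinaryGraph.from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        assert ns.modularity_q(g, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_q_invariant_under_relabeling(self, rng):
        g = random_graph(10, 0.4, rng)
        part = rng.integers(0, 3, 10)
        assert ns.modularity_q(g, part) == ns.modularity_q(g, 7 - part)


# --- brute force & networkx equivalence --------------------------------------

class TestOracleEquivalence:
    def test_small_graph_metrics_match_brute_force(self, rng):
        """Efficiency, clustering, degree, Q on 200 random <=8-node graphs."""
        for trial in range(200):
            n = int(rng.integers(2, 9))
            g = random_graph(n, float(rng.uniform(0.1, 0.9)), rng)
            a = g.adjacency()
            np.testing.assert_array_equal(ns.degree(g), a.sum(axis=1))
            assert ns.global_efficiency(g) == pytest.approx(brute_efficiency(g), abs=1e-12)
            res = ns.clustering(g)
            np.testing.assert_allclose(res.per_node, brute_clustering(g), atol=1e-12)
            if g.n_edges:
                part = ns.louvain(g, seed=trial, restarts=3)
                assert ns.modularity_q(g, part) == pytest.approx(
                    brute_modularity(g, part.assignment), abs=1e-12
                )

    def test_metrics_match_networkx(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 30))
            g = random_graph(n, 0.3, rng)
            h = nx.Graph()
            h.add_nodes_from(range(n))
            h.add_edges_from(g.edges)
            assert ns.global_efficiency(g) == pytest.approx(nx.global_efficiency(h))
            assert ns.clustering(g).mean == pytest.approx(nx.average_clustering(h))
            if g.n_edges:
                part = ns.louvain(g, seed=1, restarts=3)
                comms = [set(np.flatnonzero(part.assignment == c))
                         for c in range(part.n_modules)]
                assert part.q == pytest.approx(nx.community.modularity(h, comms))


# --- louvain -----------------------------------------------------------------

class TestLouvain:
    def test_two_disconnected_cliques(self):
        edges = list(itertools.combinations(range(5), 2)) + [
            (a + 5, b + 5) for a, b in itertools.combinations(range(5), 2)
        ]
        g = BinaryGraph.from_edges(10, edges)
        part = ns.louvain(g, seed=0)
        assert part.n_modules == 2
        assert part.q == pytest.approx(0.5)

    def test_complete_graph_single_module(self):
        part = ns.louvain(complete_graph(8), seed=0)
        assert part.n_modules == 1 and part.q == 0.0

    def test_planted_blocks_recovered(self, rng):
        n, b = 60, 4
        truth = np.repeat(np.arange(b), n // b)
        iu, ju = np.triu_indices(n, k=1)
        p = np.where(truth[iu] == truth[ju], 0.9, 0.05)
        keep = rng.random(iu.size) < p
        g = BinaryGraph(n, iu[keep].astype(np.int64) * n + ju[keep])
        part = ns.louvain(g, seed=3)
        assert adjusted_rand_score(truth, part.assignment) == 1.0

    def test_returned_q_is_exact(self, rng):
        g = random_graph(25, 0.2, rng)
        part = ns.louvain(g, seed=5)
        assert part.q == ns.modularity_q(g, part.assignment)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            ns.louvain(BinaryGraph(5, []))


# --- random references -------------------------------------------------------

class TestRandomReference:
    def test_complete_graph_forced(self):
        ref = ns.random_reference(6, 15, reps=5, seed=0)
        assert ref.efficiency == 1.0 and ref.clustering == 1.0

    def test_er_clustering_matches_density(self):
        ref = ns.random_reference(50, 245, reps=60, seed=1)
        # E[C] = density for G(n, m); 3 SE Monte-Carlo band
        assert abs(ref.clustering - 0.2) < 0.02

    def test_deterministic(self):
        a = ns.random_reference(20, 50, reps=10, seed=4)
        b = ns.random_reference(20, 50, reps=10, seed=4)
        assert (a.efficiency, a.clustering, a.modularity) == \
               (b.efficiency, b.clustering, b.modularity)

    def test_infeasible_edge_count_rejected(self):
        with pytest.raises(ValueError):
            ns.random_reference(5, 11, reps=2)

    def test_rewired_reference_preserves_degrees(self, rng):
        g = random_graph(30, 0.25, rng)
        rw = maslov_sneppen(g, swaps_per_edge=10, seed=2)
        np.testing.assert_array_equal(np.sort(ns.degree(rw)), np.sort(ns.degree(g)))
        np.testing.assert_array_equal(ns.degree(rw), ns.degree(g))
        assert rw.n_edges == g.n_edges
        assert rw.edges != g.edges  # rewiring actually moved edges


# --- sweep -------------------------------------------------------------------

class TestSweep:
    def test_default_grid_has_35_levels(self):
        grid = sparsity_grid()
        assert grid.size == 35
        assert grid[0] == 0.06 and grid[-1] == 0.40

    def test_efficiency_monotone_in_sparsity(self, rng):
        w = random_symmetric(40, rng)
        df = ns.sparsity_sweep(w, metrics=["efficiency"], grid=[0.1, 0.2, 0.3, 0.4])
        vals = df["value"].to_numpy()
        assert np.all(np.diff(vals) >= 0)

    def test_sweep_reproduces_pointwise_calls(self, small_pair):
        task, _, _ = small_pair
        grid = [0.15, 0.25]
        df = ns.sparsity_sweep(task, metrics=["efficiency", "clustering"], grid=grid)
        for s in grid:
            g = ns.threshold_sparsity(task, s)
            sub = df[df["sparsity"] == s].set_index("metric")["value"]
            assert sub["efficiency"] == metric_value(g, "efficiency")
            assert sub["clustering"] == metric_value(g, "clustering")

    def test_small_world_relative_to_random(self, small_pair):
        """A modular graph at s=0.2: higher clustering, lower efficiency
        than its G(n, m) reference."""
        _, rest, _ = small_pair
        g = ns.threshold_sparsity(rest, 0.2)
        ref = ns.random_reference(g.n_nodes, g.n_edges, reps=30, seed=0)
        assert ns.clustering(g).mean > ref.clustering
        assert ns.global_efficiency(g) < ref.efficiency
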