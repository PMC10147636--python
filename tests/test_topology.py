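"""Weighted graph topology: thresholding, L, C, Q against brute-force oracles."""

import itertools

import numpy as np
import pytest

from rsconn.topology import (
    TopologyCurves,
    characteristic_path_length,
    clustering_coefficient,
    default_density_grid,
    metric_curves,
    metric_means,
    modularity,
    proportional_threshold,
)
from rsconn._utils import vec_to_mat


def _random_weighted_graph(rng, n, p=0.6):
    vec = np.where(rng.random(n * (n - 1) // 2) < p, rng.random(n * (n - 1) // 2) + 0.05, 0.0)
    return vec_to_mat(vec, n)


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation)
# ---------------------------------------------------------------------------

def _oracle_path_length(adj):
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(n):
            if adj[i, j] > 0:
                dist[i, j] = 1.0 / adj[i, j]
    for k in range(n):  # Floyd-Warshall, written out
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    return dist[finite].mean()


def _oracle_clustering(adj):
    n = adj.shape[0]
    w = adj / adj.max()
    c = np.zeros(n)
    for i in range(n):
        neigh = [j for j in range(n) if adj[i, j] > 0]
        k = len(neigh)
        if k < 2:
            continue
        total = 0.0
        for a, b in itertools.combinations(neigh, 2):
            if adj[a, b] > 0:
                total += (w[i, a] * w[i, b] * w[a, b]) ** (1 / 3)
        c[i] = 2 * total / (k * (k - 1))
    return c.mean()


def _oracle_modularity_max(adj):
    """Exhaustive search over all partitions (Bell number; keep n small)."""
    n = adj.shape[0]
    two_m = adj.sum()
    deg = adj.sum(axis=1)

    def q_of(labels):
        labels = np.asarray(labels)
        q = 0.0
        for c in set(labels):
            mask = labels == c
            q += adj[np.ix_(mask, mask)].sum() / two_m - (deg[mask].sum() / two_m) ** 2
        return q

    def partitions(elements):
        if not elements:
            yield []
            return
        first, rest = elements[0], elements[1:]
        for smaller in partitions(rest):
            for i, subset in enumerate(smaller):
                yield smaller[:i] + [[first] + subset] + smaller[i + 1 :]
            yield [[first]] + smaller

    best = -1.0
    for part in partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for ci, block in enumerate(part):
            labels[block] = ci
        best = max(best, q_of(labels))
    return best


# ---------------------------------------------------------------------------


class TestProportionalThreshold:
    def test_full_density_keeps_positives_drops_negatives(self, rng):
        vec = rng.normal(0, 1, 45)
        mat = vec_to_mat(vec, 10)
        g = proportional_threshold(mat, 1.0)
        assert g.n_edges == int((vec > 0).sum())
        assert np.all(g.adjacency >= 0)
        assert g.truncated  # fewer positive edges than n(n-1)/2

    def test_edge_count_formula_at_study_density(self, rng):
        mat = vec_to_mat(rng.random(94 * 93 // 2) + 0.01, 94)
        g = proportional_threshold(mat, 0.05)
        assert g.n_edges == 219  # round(0.05 * 4371)

    def test_tied_weights_resolved_deterministically(self):
        # six edges, four tied at the cutoff weight; k = 3 keeps the two
        # stronger edges plus the smallest-indexed tied edge
        vec = np.array([0.9, 0.8, 0.5, 0.5, 0.5, 0.5])
        mat = vec_to_mat(vec, 4)  # edges in (0,1),(0,2),(0,3),(1,2),(1,3),(2,3) order
        g1 = proportional_threshold(mat, 0.5)
        g2 = proportional_threshold(mat, 0.5)
        assert g1.n_edges == 3
        assert np.array_equal(g1.adjacency, g2.adjacency)
        assert g1.adjacency[0, 3] == 0.5  # smallest-indexed tied pair wins
        assert g1.adjacency[1, 2] == 0.0

    def test_density_out_of_range(self, rng):
        with pytest.raises(ValueError):
            proportional_threshold(np.eye(4), 0.0)
        with pytest.raises(ValueError):
            proportional_threshold(np.eye(4), 1.2)


class TestPathLength:
    def test_triangle_direct_edges(self):
        adj = vec_to_mat(np.array([0.5, 0.5, 0.5]), 3)
        assert characteristic_path_length(adj) == pytest.approx(2.0)

    def test_three_node_chain(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 1.0
        adj[1, 2] = adj[2, 1] = 1.0
        assert characteristic_path_length(adj) == pytest.approx(4 / 3)

    def test_disconnected_pairs_excluded(self):
        adj = np.zeros((4, 4))
        adj[0, 1] = adj[1, 0] = 1.0
        adj[2, 3] = adj[3, 2] = 1.0
        l_val, frac = characteristic_path_length(adj, return_unreachable=True)
        assert l_val == pytest.approx(1.0)
        assert frac == pytest.approx(2 / 3)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            characteristic_path_length(np.zeros((3, 3)))


class TestClustering:
    def test_complete_equal_weights(self):
        adj = vec_to_mat(np.full(10, 0.3), 5)
        assert clustering_coefficient(adj) == pytest.approx(1.0)

    def test_star_has_no_triangles(self):
        adj = np.zeros((5, 5))
        adj[0, 1:] = adj[1:, 0] = 0.7
        assert clustering_coefficient(adj) == pytest.approx(0.0)

    def test_unequal_weight_fixture_matches_oracle(self):
        vec = np.array([0.9, 0.4, 0.0, 0.7, 0.2, 0.5])
        adj = vec_to_mat(vec, 4)
        assert clustering_coefficient(adj) == pytest.approx(_oracle_clustering(adj), abs=1e-12)


class TestModularity:
    def test_single_clique_zero(self):
        adj = vec_to_mat(np.ones(10), 5)
        assert modularity(adj, seed=0) == pytest.approx(0.0)

    def test_two_disconnected_cliques_half(self):
        adj = np.zeros((8, 8))
        adj[:4, :4] = 1.0
        adj[4:, 4:] = 1.0
        np.fill_diagonal(adj, 0.0)
        assert modularity(adj, seed=0) == pytest.approx(0.5)

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(0)
        n = 20
        adj = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                p = 0.9 if (i < 10) == (j < 10) else 0.05
                if rng.random() < p:
                    adj[i, j] = adj[j, i] = 1.0
        q, labels = modularity(adj, seed=1, return_partition=True)
        assert q > 0.3
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_seeded_reproducibility(self, rng):
        adj = _random_weighted_graph(rng, 15)
        q1, l1 = modularity(adj, seed=42, return_partition=True)
        q2, l2 = modularity(adj, seed=42, return_partition=True)
        assert q1 == q2 and np.array_equal(l1, l2)


@pytest.mark.parametrize("seed", range(20))
def test_metrics_match_brute_force_on_small_graphs(seed):
    """L, C, Q all agree with exhaustive computations on random <= 8-node graphs."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    adj = _random_weighted_graph(rng, n)
    if not np.any(adj > 0):
        return
    assert characteristic_path_length(adj) == pytest.approx(_oracle_path_length(adj), abs=1e-10)
    if n >= 3:
        assert clustering_coefficient(adj) == pytest.approx(_oracle_clustering(adj), abs=1e-10)
    if n <= 7:
        q = modularity(adj, seed=0, n_restarts=30)
        assert q <= _oracle_modularity_max(adj) + 1e-10
        assert q >= 0.0


class TestScaleInvariance:
    def test_scaling_weights(self, rng):
        adj = _random_weighted_graph(rng, 12)
        scaled = 3.7 * adj
        assert clustering_coefficient(scaled) == pytest.approx(clustering_coefficient(adj), rel=1e-12)
        assert characteristic_path_length(scaled) == pytest.approx(characteristic_path_length(adj) / 3.7, rel=1e-12)
        assert modularity(scaled, seed=5) == pytest.approx(modularity(adj, seed=5), rel=1e-9)


class TestCurves:
    def test_default_grid_has_41_points(self):
        grid = default_density_grid()
        assert len(grid) == 41
        assert grid[0] == 0.05 and grid[-1] == 0.45

    def test_curve_table_shape_and_means(self, small_panel):
        grid = np.array([0.2, 0.3, 0.4])
        curves = metric_curves(small_panel, densities=grid, metrics=("L", "C"), seed=0)
        n_rows = len(small_panel.manifest) * len(grid) * 2
        assert len(curves) == n_rows
        means = metric_means(curves)
        one = curves.query("subject_id == 'AN001' and time_point == 'TP1' and metric == 'L'")["value"]
        got = means.query("subject_id == 'AN001' and time_point == 'TP1' and metric == 'L'")["mean_value"].iloc[0]
        assert got == pytest.approx(one.mean())

    def test_identical_connectomes_identical_curves(self, rng):
        import pandas as pd
        from rsconn.panel import CohortPanel

        mat = vec_to_mat(rng.random(435) + 0.01, 30)
        manifest = pd.DataFrame(
            [("S1", "AN", "TP1"), ("S2", "AN", "TP1")], columns=["subject_id", "group", "time_point"]
        )
        panel = CohortPanel(manifest, {("S1", "TP1"): mat, ("S2", "TP1"): mat.copy()})
        curves = metric_curves(panel, densities=np.array([0.1, 0.2]), metrics=("L", "C"), seed=0)
        wide = curves.pivot_table(index=["density", "metric"], columns="subject_id", values="value")
        assert np.allclose(wide["S1"], wide["S2"])

    def test_higher_density_never_lengthens_paths_on_connected_graphs(self, rng):
        mat = vec_to_mat(rng.random(435) + 0.05, 30)  # all positive -> connected at high density
        grid = default_density_grid()[::8]
        tf = TopologyCurves(densities=grid, metrics=("L",))
        curve = tf.transform(mat[None])[0, :, 0]
        assert np.all(np.diff(curve) <= 1e-12)

    def test_transformer_output_shape(self, small_panel):
        mats, _ = small_panel.stack(group="AN", time_point="TP1")
        out = TopologyCurves(densities=[0.2, 0.4], metrics=("L", "C"), random_state=0).fit_transform(mats[:3])
        assert out.shape == (3, 2, 2)
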