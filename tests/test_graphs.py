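"""Quantile- and visibility-graph constructions vs. brute-force oracles."""

import numpy as np
import pytest

from eegmarkers import (build_quantile_graph, build_visibility_graph,
                        complexity_index, default_quantile_count,
                        mean_jump_length, white_noise)
from eegmarkers.features.graphs import quantile_bins


def brute_force_visibility(x):
    """O(T^3) reference: check every pair against every intermediate."""
    T = len(x)
    adj = np.zeros((T, T), dtype=int)
    for i in range(T):
        for j in range(i + 1, T):
            visible = all(
                x[k] < x[j] + (x[i] - x[j]) * (j - k) / (j - i)
                for k in range(i + 1, j)
            )
            if visible:
                adj[i, j] = adj[j, i] = 1
    return adj


def enumerate_transitions(bins, Q, k):
    counts = np.zeros((Q, Q), dtype=int)
    for t in range(len(bins) - k):
        counts[bins[t], bins[t + k]] += 1
    return counts


class TestQuantileGraph:
    def test_strictly_increasing_series_is_superdiagonal(self):
        g = build_quantile_graph(np.arange(1.0, 21.0), Q=20, k=1)
        expected = np.diag(np.ones(19, dtype=int), k=1)
        assert np.array_equal(g.counts, expected)

    def test_alternating_series_swaps_quantiles(self):
        x = np.tile([0.0, 1.0], 512)
        g = build_quantile_graph(x, Q=2, k=1)
        assert np.allclose(g.transition, [[0, 1], [1, 0]])
        assert mean_jump_length(g) == pytest.approx(1.0)

    def test_alternating_series_lag2_never_jumps(self):
        x = np.tile([0.0, 1.0], 512)
        g = build_quantile_graph(x, Q=2, k=2)
        assert mean_jump_length(g) == pytest.approx(0.0)

    def test_increasing_five_points_jump(self):
        g = build_quantile_graph(np.arange(1.0, 6.0), Q=5, k=1)
        assert mean_jump_length(g) == pytest.approx(0.8)

    def test_constant_series_occupies_one_bin(self):
        g = build_quantile_graph(np.full(100, 2.5), Q=4, k=1)
        assert g.counts.sum() == 99
        nz = np.argwhere(g.counts > 0)
        assert len(nz) == 1 and nz[0][0] == nz[0][1]

    def test_counts_total_and_row_stochasticity(self, rng):
        x = rng.standard_normal(500)
        g = build_quantile_graph(x, Q=12, k=7)
        assert g.counts.sum() == 500 - 7
        rowsum = g.transition.sum(axis=1)
        occupied = g.counts.sum(axis=1) > 0
        assert np.allclose(rowsum[occupied], 1.0)
        assert np.allclose(rowsum[~occupied], 0.0)

    def test_counts_match_direct_enumeration(self, rng):
        for trial in range(20):
            x = rng.standard_normal(rng.integers(30, 200))
            Q = int(rng.integers(2, 15))
            k = int(rng.integers(1, 5))
            g = build_quantile_graph(x, Q=Q, k=k)
            bins = quantile_bins(x, Q)
            assert np.array_equal(g.counts, enumerate_transitions(bins, Q, k))

    def test_quantile_count_rule(self):
        assert default_quantile_count(1024) == 20

    def test_invalid_lag_rejected(self):
        with pytest.raises(ValueError):
            build_quantile_graph(np.arange(10.0), Q=2, k=10)

    def test_shift_scale_invariance_of_jump_length(self, rng):
        x = rng.standard_normal(300)
        d0 = mean_jump_length(build_quantile_graph(x, 10, 2))
        d1 = mean_jump_length(build_quantile_graph(3.0 * x + 7.0, 10, 2))
        assert d1 == pytest.approx(d0)


class TestVisibilityGraph:
    def test_convex_series_is_complete(self):
        x = np.arange(50.0) ** 2
        adj = build_visibility_graph(x).to_dense()
        assert np.array_equal(adj, 1 - np.eye(50, dtype=int))

    def test_five_point_example(self):
        x = [0.8, 0.2, 0.6, 0.1, 0.9]
        adj = build_visibility_graph(x).to_dense()
        edges = {(i + 1, j + 1) for i in range(5) for j in range(i + 1, 5)
                 if adj[i, j]}
        assert edges == {(1, 2), (2, 3), (3, 4), (4, 5), (1, 3), (1, 5), (3, 5)}

    def test_path_subgraph_always_present(self, rng):
        x = rng.standard_normal(80)
        adj = build_visibility_graph(x).to_dense()
        assert np.all(np.diag(adj, k=1) == 1)

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(50):
            T = int(rng.integers(10, 201))
            x = rng.standard_normal(T)
            adj = build_visibility_graph(x).to_dense()
            assert np.array_equal(adj, brute_force_visibility(x))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            build_visibility_graph([1.0])


class TestComplexityIndex:
    def test_complete_graph_scores_zero(self):
        adj = build_visibility_graph(np.arange(30.0) ** 2)
        assert complexity_index(adj) == pytest.approx(0.0, abs=1e-9)

    def test_path_graph_scores_zero(self):
        # a strictly concave series yields the pure path graph
        x = -(np.arange(40.0) - 20.0) ** 2
        adj = build_visibility_graph(x)
        assert adj.n_edges == 39
        assert complexity_index(adj) == pytest.approx(0.0, abs=1e-9)

    def test_matches_definition_from_dense_eigenvalue(self, rng):
        x = rng.standard_normal(120)
        adj = build_visibility_graph(x)
        lam = np.linalg.eigvalsh(adj.to_dense().astype(float))[-1]
        N = adj.n
        lo = 2 * np.cos(np.pi / (N + 1))
        c = (lam - lo) / (N - 1 - lo)
        assert complexity_index(adj) == pytest.approx(4 * c * (1 - c), abs=1e-9)

    def test_index_bounded_in_unit_interval(self, rng):
        for _ in range(10):
            x = rng.standard_normal(150)
            assert 0.0 <= complexity_index(build_visibility_graph(x)) <= 1.0

    def test_shift_scale_invariance(self, rng):
        x = rng.standard_normal(200)
        i0 = complexity_index(build_visibility_graph(x))
        i1 = complexity_index(build_visibility_graph(2.5 * x - 3.0))
        assert i1 == pytest.approx(i0, abs=1e-9)

    def test_sparse_and_dense_eigensolvers_agree(self):
        x = white_noise(400, seed=3)  # above the dense cutoff
        adj = build_visibility_graph(x)
        lam_dense = np.linalg.eigvalsh(adj.to_dense().astype(float))[-1]
        N = adj.n
        lo = 2 * np.cos(np.pi / (N + 1))
        c = (lam_dense - lo) / (N - 1 - lo)
        assert complexity_index(adj) == pytest.approx(4 * c * (1 - c), abs=1e-8)
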