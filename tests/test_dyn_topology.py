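"""Graph metrics vs independent oracles; thresholding; AUC and CV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dynconn as dc


def random_corr(rng, n):
    A = rng.uniform(-1, 1, (n, n))
    C = (A + A.T) / 2
    np.fill_diagonal(C, 1.0)
    return C


def floyd_warshall_inverse_weight(W):
    """Brute-force all-pairs shortest paths with edge length 1/weight."""
    n = W.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if W[i, j] > 0:
                d[i, j] = 1.0 / W[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


class TestThresholdTopk:
    def test_hand_sorted_four_nodes(self):
        C = np.eye(4)
        vals = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.7, (1, 2): 0.3,
                (1, 3): 0.2, (2, 3): 0.1}
        for (i, j), v in vals.items():
            C[i, j] = C[j, i] = v
        A, short = dc.threshold_topk(C, 50)  # m = round(0.5 * 6) = 3
        kept = sorted(A[np.triu_indices(4, 1)][A[np.triu_indices(4, 1)] > 0])
        np.testing.assert_allclose(kept, [0.7, 0.8, 0.9])
        assert not short

    def test_all_negative_gives_empty_graph_with_flag(self):
        C = -0.5 * np.ones((4, 4))
        np.fill_diagonal(C, 1.0)
        A, short = dc.threshold_topk(C, 20)
        assert short
        assert not np.any(A)

    def test_k100_keeps_all_positive_edges(self, rng):
        C = np.abs(random_corr(rng, 6))
        A, short = dc.threshold_topk(C, 100)
        offdiag = ~np.eye(6, dtype=bool)
        np.testing.assert_allclose(A[offdiag], C[offdiag])
        assert not short

    def test_weights_retained_unchanged(self, rng):
        C = random_corr(rng, 8)
        A, _ = dc.threshold_topk(C, 15)
        nz = A > 0
        np.testing.assert_array_equal(A[nz], C[nz])
        np.testing.assert_allclose(np.diag(A), 0.0)

    def test_tie_break_by_lexicographic_pair(self):
        C = np.eye(4)
        # all positive weights equal: budget 2 keeps (0,1) and (0,2)
        C[C == 0] = 0.5
        A, _ = dc.threshold_topk(C, 100 * 2 / 6)
        assert A[0, 1] == 0.5 and A[0, 2] == 0.5
        assert A[2, 3] == 0.0


class TestEfficiency:
    def test_complete_unit_graph(self):
        W = np.ones((5, 5)) - np.eye(5)
        assert dc.global_efficiency(W) == pytest.approx(1.0)
        np.testing.assert_allclose(dc.nodal_efficiency(W), 1.0)

    def test_two_disconnected_dyads(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        np.testing.assert_allclose(dc.nodal_efficiency(W), 1.0 / 3)
        assert dc.global_efficiency(W) == pytest.approx(1.0 / 3)

    def test_negative_weight_rejected(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = -0.2
        with pytest.raises(ValueError, match="negative"):
            dc.nodal_efficiency(W)

    def test_matches_floyd_warshall_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 11))
            A, _ = dc.threshold_topk(random_corr(rng, n), float(rng.uniform(10, 60)))
            d = floyd_warshall_inverse_weight(A)
            inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1), 0.0)
            np.fill_diagonal(inv, 0.0)
            np.testing.assert_allclose(
                dc.nodal_efficiency(A), inv.sum(axis=1) / (n - 1), atol=1e-12
            )


class TestClustering:
    def test_unit_triangle(self):
        W = np.ones((3, 3)) - np.eye(3)
        assert dc.clustering_coefficient(W) == pytest.approx(1.0)

    def test_star_graph_has_no_triangles(self):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 1.0
        assert dc.clustering_coefficient(W) == pytest.approx(0.0)

    def test_weighted_triangle_closed_form(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[0, 2] = W[2, 0] = 0.5
        W[1, 2] = W[2, 1] = 1.0
        # after max-normalization every node's coefficient is (0.25)^(1/3)
        expected = (0.5 * 0.5 * 1.0) ** (1 / 3)
        assert dc.clustering_coefficient(W) == pytest.approx(expected)

    def test_matches_networkx_onnela(self, rng):
        import networkx as nx

        for _ in range(25):
            n = int(rng.integers(4, 10))
            A, _ = dc.threshold_topk(random_corr(rng, n), 50)
            if not np.any(A > 0):
                continue
            G = nx.from_numpy_array(A / A.max())
            cc = nx.clustering(G, weight="weight")
            expected = np.mean([cc[i] for i in range(n)])
            assert dc.clustering_coefficient(A) == pytest.approx(expected, abs=1e-10)


class TestEigenvectorCentrality:
    def test_complete_unit_graph_uniform(self):
        W = np.ones((6, 6)) - np.eye(6)
        np.testing.assert_allclose(
            dc.eigenvector_centrality(W), 1 / np.sqrt(6), atol=1e-9
        )

    def test_star_hub_leaf_ratio(self):
        # star with 4 leaves: hub 2/sqrt(8), each leaf 1/sqrt(8)
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 1.0
        ec = dc.eigenvector_centrality(W)
        assert ec[0] / ec[1] == pytest.approx(2.0, abs=1e-8)
        assert ec[0] == pytest.approx(2 / np.sqrt(8), abs=1e-8)

    def test_matches_dense_eigendecomposition(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 11))
            A, _ = dc.threshold_topk(random_corr(rng, n), float(rng.uniform(20, 80)))
            if not np.any(A > 0):
                continue
            ec = dc.eigenvector_centrality(A)
            vals, vecs = np.linalg.eigh(A)
            v = np.abs(vecs[:, -1])
            v /= np.linalg.norm(v)
            # skip near-degenerate leading pairs that power iteration
            # cannot resolve within its iteration budget
            rel_gap = (vals[-1] - vals[-2]) / (vals[-1] + A.sum(axis=1).max())
            if rel_gap < 0.02:
                continue
            np.testing.assert_allclose(ec, v, atol=1e-7)
            assert np.all(ec >= 0)
            assert np.linalg.norm(ec) == pytest.approx(1.0)

    def test_zero_matrix_gives_zero_vector(self):
        np.testing.assert_array_equal(
            dc.eigenvector_centrality(np.zeros((4, 4))), np.zeros(4)
        )


class TestAucAndCv:
    def test_constant_auc_is_rectangle(self):
        assert dc.auc_over_sparsity([3.0] * 4, (5, 10, 15, 20)) == pytest.approx(45.0)

    def test_triangle(self):
        assert dc.auc_over_sparsity([0.0, 1.0], (5, 10)) == pytest.approx(2.5)

    def test_matches_independent_trapezoid(self, rng):
        v = rng.uniform(0, 2, 4)
        k = np.array([5.0, 10.0, 15.0, 20.0])
        manual = sum(
            (v[i] + v[i + 1]) / 2 * (k[i + 1] - k[i]) for i in range(3)
        )
        assert dc.auc_over_sparsity(v, k) == pytest.approx(manual, abs=1e-12)

    def test_cv_constant_series_is_zero(self):
        assert dc.cv_over_windows(np.full(10, 2.5)) == pytest.approx(0.0)

    def test_cv_hand_value(self):
        assert dc.cv_over_windows(np.array([1.0, 3.0])) == pytest.approx(
            np.sqrt(2) / 2
        )

    def test_cv_near_zero_mean_undefined(self):
        assert np.isnan(dc.cv_over_windows(np.array([1e-15, -1e-15])))

    def test_single_window_raises(self):
        with pytest.raises(ValueError):
            dc.cv_over_windows(np.array([1.0]))

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.1, 100.0), st.integers(0, 2**31 - 1))
    def test_cv_scale_invariant(self, c, seed):
        rng = np.random.default_rng(seed)
        series = rng.uniform(0.5, 2.0, 12)
        assert dc.cv_over_windows(c * series) == pytest.approx(
            dc.cv_over_windows(series), rel=1e-9
        )


class TestMonotonicityAndBounds:
    def test_denser_threshold_never_decreases_global_efficiency(self, rng):
        C = np.abs(random_corr(rng, 12))
        effs = [
            dc.global_efficiency(dc.threshold_topk(C, K)[0])
            for K in (5, 10, 15, 20, 40)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(effs, effs[1:]))

    def test_metric_ranges_for_unit_interval_weights(self, rng):
        for _ in range(20):
            A, _ = dc.threshold_topk(random_corr(rng, 8), 40)
            assert 0 <= dc.global_efficiency(A) <= 1 + 1e-12
            assert np.all(dc.nodal_efficiency(A) <= 1 + 1e-12)
            assert 0 <= dc.clustering_coefficient(A) <= 1 + 1e-12


class TestSubjectPipeline:
    def test_topo_dynamics_shapes_and_flags(self, rng):
        data = rng.standard_normal((60, 8))
        series = dc.sliding_window_fc(data, dc.WindowParams(width_tr=20))
        td = dc.subject_topo_dynamics(series)
        assert td.cv_nodal_efficiency.shape == (8,)
        assert td.cv_eigenvector_centrality.shape == (8,)
        table = dc.dyn_topology.topo_table([td])
        assert len(table) == 2 + 2 * 8
        assert set(table["metric"]) == {
            "global_efficiency",
            "clustering_coefficient",
            "nodal_efficiency",
            "eigenvector_centrality",
        }
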