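import numpy as np
import pytest

from fatiguenet.data_model import DEFAULT_BANDS, default_montage
from fatiguenet.network import (
    ConnectivityNetwork,
    binarize_by_sparsity,
    characteristic_path_length,
    clustering_coefficient,
    fc_matrix,
    hemisphere_means,
    matched_random_networks,
    node_clustering,
    small_worldness,
)
from fatiguenet.preprocess import BandRoiSeries

from conftest import random_weight_matrix

ROI8 = ("L-PFC", "M-PFC", "R-PFC", "L-FEF", "R-FEF", "SMA", "L-PMC", "R-PMC")


def brute_force_clustering(w):
    """Independent O(n^3) evaluation of the weighted clustering mean."""
    n = w.shape[0]
    wh = w / w.max()
    total = 0.0
    for u in range(n):
        nbrs = [v for v in range(n) if w[u, v] > 0]
        if len(nbrs) < 2:
            continue
        s = 0.0
        for v in nbrs:
            for t in nbrs:
                if v != t:
                    s += (wh[u, v] * wh[u, t] * wh[v, t]) ** (1 / 3)
        total += s / (len(nbrs) * (len(nbrs) - 1))
    return total / n


def brute_force_path_length(w):
    """Floyd-Warshall all-pairs mean shortest path (length = 1/weight)."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    off = ~np.eye(n, dtype=bool)
    vals = d[off]
    return vals[np.isfinite(vals)].mean()


def _series(y):
    return BandRoiSeries(
        y=y, roi_order=ROI8[: y.shape[1]], species="HbO", band=DEFAULT_BANDS[1], fs=16.0
    )


class TestFcMatrix:
    def test_perfect_linear_dependence(self, rng):
        x = rng.standard_normal(100)
        y = np.column_stack([x, 2 * x] + [rng.standard_normal(100) for _ in range(6)])
        net = fc_matrix(_series(y))
        assert net.r[0, 1] == pytest.approx(1.0)
        assert net.w[0, 1] == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 3.0, 2.0])
        rest = np.tile(np.array([1.0, 2.0, 4.0])[:, None], (1, 6))
        rest += np.arange(6) * 0.001 * np.array([1.0, -2.0, 1.0])[:, None]
        net = fc_matrix(_series(np.column_stack([x, y, rest])))
        assert net.r[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_anticorrelation_maps_to_unit_weight(self, rng):
        x = rng.standard_normal(50)
        y = np.column_stack([x, -x] + [rng.standard_normal(50) for _ in range(6)])
        net = fc_matrix(_series(y))
        assert net.r[0, 1] == pytest.approx(-1.0)
        assert net.w[0, 1] == pytest.approx(1.0)

    def test_zero_variance_column_named(self, rng):
        y = rng.standard_normal((50, 8))
        y[:, 3] = 2.5
        with pytest.raises(ValueError, match="L-FEF"):
            fc_matrix(_series(y))


class TestClustering:
    def test_equal_weight_triangle_is_one(self):
        w = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]])
        for u in range(3):
            assert node_clustering(w, u) == pytest.approx(1.0)

    def test_unbalanced_triangle_hand_value(self):
        w = np.array([[0, 1, 1], [1, 0, 0.5], [1, 0.5, 0.0]])
        assert node_clustering(w, 0) == pytest.approx(0.5 ** (1 / 3), abs=1e-12)

    def test_star_center_has_no_triangles(self):
        w = np.zeros((4, 4))
        w[0, 1:] = w[1:, 0] = 1.0
        assert node_clustering(w, 0) == 0.0

    def test_edgeless_graph_zero_mean(self):
        assert clustering_coefficient(np.zeros((4, 4))) == 0.0

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 9))
            w = random_weight_matrix(rng, n)
            assert clustering_coefficient(w) == pytest.approx(
                brute_force_clustering(w), abs=1e-12
            )


class TestPathLength:
    def test_complete_graph_constant_weights(self):
        w = np.full((4, 4), 0.5)
        np.fill_diagonal(w, 0.0)
        L, disconnected = characteristic_path_length(w)
        assert L == pytest.approx(2.0) and not disconnected

    def test_path_graph_hand_value(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        L, _ = characteristic_path_length(w)
        assert L == pytest.approx(4.0 / 3.0)

    def test_matches_floyd_warshall_on_random_graphs(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 9))
            w = random_weight_matrix(rng, n)
            L, _ = characteristic_path_length(w)
            assert L == pytest.approx(brute_force_path_length(w), abs=1e-12)

    def test_disconnected_flag(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        L, disconnected = characteristic_path_length(w)
        assert disconnected and L == pytest.approx(1.0)


class TestScalingInvariance:
    def test_clustering_invariant_path_reciprocal(self, rng):
        w = random_weight_matrix(rng, 8)
        c = 3.7
        assert clustering_coefficient(c * w) == pytest.approx(
            clustering_coefficient(w), rel=1e-12
        )
        L1, _ = characteristic_path_length(w)
        L2, _ = characteristic_path_length(c * w)
        assert L2 == pytest.approx(L1 / c, rel=1e-12)

    def test_sigma_invariant_to_weight_scale(self, rng):
        w = random_weight_matrix(rng, 8)
        m1 = small_worldness(w, n_random=20, seed=5)
        m2 = small_worldness(4.2 * w, n_random=20, seed=5)
        assert m2.sigma == pytest.approx(m1.sigma, rel=1e-9)


class TestBinarize:
    def test_eight_nodes_default_sparsity_keeps_13(self, rng):
        w = random_weight_matrix(rng, 8)
        adj = binarize_by_sparsity(w, 0.45)
        assert adj.sum() // 2 == 13  # round(0.45 * 28) = round(12.6)

    def test_full_sparsity_keeps_complete_graph(self, rng):
        w = random_weight_matrix(rng, 8) + 0.01
        np.fill_diagonal(w, 0.0)
        assert binarize_by_sparsity(w, 1.0).sum() // 2 == 28

    def test_exact_edge_count_for_any_input(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 9))
            w = random_weight_matrix(rng, n)
            sparsity = float(rng.uniform(0.2, 1.0))
            k = int(np.floor(sparsity * n * (n - 1) / 2 + 0.5))
            if k == 0:
                continue
            assert binarize_by_sparsity(w, sparsity).sum() // 2 == k

    def test_tie_break_deterministic(self):
        w = np.full((8, 8), 0.5)
        np.fill_diagonal(w, 0.0)
        a = binarize_by_sparsity(w, 0.45)
        b = binarize_by_sparsity(w, 0.45)
        np.testing.assert_array_equal(a, b)

    def test_zero_edges_rejected(self):
        w = np.zeros((8, 8))
        w[0, 1] = w[1, 0] = 1.0
        with pytest.raises(ValueError, match="sparsity"):
            binarize_by_sparsity(w, 0.01)


class TestMatchedRandomNetworks:
    def test_degree_sequence_preserved(self, rng):
        w = (random_weight_matrix(rng, 8) > 0.8) * random_weight_matrix(rng, 8)
        w = np.triu(w, 1)
        w = w + w.T
        if (w > 0).sum() < 4:
            w[0, 1] = w[1, 0] = 0.5
            w[2, 3] = w[3, 2] = 0.5
        deg = (w > 0).sum(axis=1)
        for null in matched_random_networks(w, n_random=20, seed=9):
            np.testing.assert_array_equal((null > 0).sum(axis=1), deg)

    def test_weight_multiset_preserved(self, rng):
        w = random_weight_matrix(rng, 8)
        w *= binarize_by_sparsity(w, 0.45)
        orig = np.sort(w[np.triu_indices(8, 1)])
        for null in matched_random_networks(w, n_random=20, seed=9, mode="weighted"):
            np.testing.assert_allclose(np.sort(null[np.triu_indices(8, 1)]), orig)

    def test_modular_network_loses_clustering_under_null(self):
        """Rewiring a strongly modular sparse network destroys its triangles
        on average (checked over 10 master seeds)."""
        w = np.zeros((8, 8))
        for block in ((0, 1, 2, 3), (4, 5, 6, 7)):
            for i in block:
                for j in block:
                    if i != j:
                        w[i, j] = 1.0
        w[0, 4] = w[4, 0] = 0.2
        c_real = clustering_coefficient(w)
        wins = 0
        for seed in range(10):
            nulls = matched_random_networks(w, n_random=100, seed=seed)
            c_null = np.mean([clustering_coefficient(m) for m in nulls])
            wins += c_null < c_real
        assert wins >= 9


class TestSmallWorldness:
    def test_sigma_is_gamma_over_lambda(self, rng):
        w = random_weight_matrix(rng, 8)
        m = small_worldness(w, n_random=30, seed=2)
        assert m.sigma == pytest.approx(m.gamma / m.lam, abs=1e-12)

    def test_random_graph_sigma_near_one(self):
        """An unstructured Erdos-Renyi-like weighted graph is statistically
        its own null: the mean sigma over 10 realizations lies in [0.8, 1.2].
        Individual 8-node realizations fluctuate around 1 because a single
        small graph is not its ensemble mean."""
        sigmas = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            w = np.zeros((8, 8))
            iu, ju = np.triu_indices(8, 1)
            vals = rng.uniform(0.3, 1.0, 28) * (rng.random(28) < 0.55)
            w[iu, ju] = vals
            w[ju, iu] = vals
            if (w > 0).sum(axis=0).min() == 0:
                w[0, 1] = w[1, 0] = 0.5
            sigmas.append(small_worldness(w, n_random=50, seed=seed).sigma)
        assert 0.8 <= np.mean(sigmas) <= 1.2

    def test_ring_lattice_with_chords_is_small_world(self):
        """The clustered-ring-plus-shortcuts analog of a Watts-Strogatz
        network shows sigma > 1 in every seed."""
        w = np.zeros((8, 8))
        for i in range(8):
            w[i, (i + 1) % 8] = w[(i + 1) % 8, i] = 1.0
            w[i, (i + 2) % 8] = w[(i + 2) % 8, i] = 0.8
        w[0, 4] = w[4, 0] = 0.6
        w[2, 6] = w[6, 2] = 0.6
        sigmas = [small_worldness(w, n_random=50, seed=s).sigma for s in range(10)]
        assert all(s > 1 for s in sigmas)

    def test_unweighted_mode_binarizes(self, rng):
        w = random_weight_matrix(rng, 8)
        m = small_worldness(w, n_random=20, seed=3, mode="unweighted")
        assert m.mode == "unweighted"
        assert m.C <= 1.0 + 1e-12


class TestHemisphereMeans:
    def test_constant_matrix(self, montage):
        w = np.full((8, 8), 0.4)
        np.fill_diagonal(w, 0.0)
        net = ConnectivityNetwork(r=w.copy(), w=w, roi_order=ROI8)
        left, right = hemisphere_means(net, montage)
        assert left == pytest.approx(0.4) and right == pytest.approx(0.4)

    def test_hand_set_matrix(self, montage):
        w = np.zeros((8, 8))
        # left pairs: (L-PFC, L-FEF)=(0,3), (L-PFC, L-PMC)=(0,6), (L-FEF, L-PMC)=(3,6)
        w[0, 3] = w[3, 0] = 0.6
        w[0, 6] = w[6, 0] = 0.3
        w[3, 6] = w[6, 3] = 0.9
        # right pairs: (2,4), (2,7), (4,7)
        w[2, 4] = w[4, 2] = 0.2
        w[2, 7] = w[7, 2] = 0.4
        w[4, 7] = w[7, 4] = 0.6
        net = ConnectivityNetwork(r=w.copy(), w=w, roi_order=ROI8)
        left, right = hemisphere_means(net, montage)
        assert left == pytest.approx(0.6)
        assert right == pytest.approx(0.4)
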