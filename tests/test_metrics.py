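"""Weighted graph metrics against hand-derived values and brute-force oracles."""

import numpy as np
import pytest

from devconnectome import metrics as m
from devconnectome.io import Connectome

import oracles

K3 = np.ones((3, 3)) - np.eye(3)
P3 = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
P3_W2 = 2 * P3
STAR4 = np.zeros((5, 5))
STAR4[0, 1:] = STAR4[1:, 0] = 1.0
DYADS = np.zeros((4, 4))
DYADS[0, 1] = DYADS[1, 0] = 1.0
DYADS[2, 3] = DYADS[3, 2] = 1.0
C4 = np.array(
    [[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]], float
)


class TestHandValues:
    def test_shortest_paths_reciprocal_weights(self):
        d = m.shortest_paths(P3_W2)
        assert d[0, 1] == pytest.approx(0.5)
        assert d[0, 2] == pytest.approx(1.0)

    def test_disconnected_pairs_infinite(self):
        d = m.shortest_paths(DYADS)
        assert np.isinf(d[0, 2])

    @pytest.mark.parametrize(
        "W, expected",
        [(K3, 1.0), (P3, 5.0 / 6.0), (np.zeros((3, 3)), 0.0)],
    )
    def test_global_efficiency(self, W, expected):
        assert m.global_efficiency(W) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "W, expected",
        [(K3, 1.0), (P3, 4.0 / 3.0)],
    )
    def test_characteristic_path_length(self, W, expected):
        assert m.characteristic_path_length(W) == pytest.approx(expected)

    def test_path_length_disconnected_restricts_to_finite(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="devconnectome.metrics"):
            lp = m.characteristic_path_length(DYADS)
        assert lp == pytest.approx(1.0)
        assert any("disconnected" in r.message for r in caplog.records)

    def test_path_length_all_disconnected_errors(self):
        with pytest.raises(ValueError, match="no connected"):
            m.characteristic_path_length(np.zeros((3, 3)))

    def test_strength(self):
        np.testing.assert_allclose(m.degree_strength(P3_W2), [2, 4, 2])
        assert m.network_strength(P3_W2) == pytest.approx(8.0 / 3.0)
        assert m.network_strength(np.zeros((3, 3))) == 0.0

    def test_clustering_k3_variants(self):
        c, ci = m.clustering_coefficient(K3)
        np.testing.assert_allclose(ci, 1.0)
        W = np.array([[0, 4, 1], [4, 0, 1], [1, 1, 0]], float)
        _, ci = m.clustering_coefficient(W)
        expected = (1.0 * 0.25 * 0.25) ** (1.0 / 3.0)  # after scaling by max=4
        np.testing.assert_allclose(ci, expected)

    def test_clustering_isolated_and_degree_one_zero(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0  # nodes 2,3 isolated; 0,1 have one connection
        _, ci = m.clustering_coefficient(W)
        np.testing.assert_array_equal(ci, 0.0)

    def test_local_efficiency_cases(self):
        np.testing.assert_allclose(m.nodal_local_efficiency(K3), 1.0)
        assert m.local_efficiency(K3) == pytest.approx(1.0)
        np.testing.assert_array_equal(m.nodal_local_efficiency(P3), 0.0)
        np.testing.assert_array_equal(m.nodal_local_efficiency(STAR4), 0.0)

    def test_nodal_efficiency_p3(self):
        np.testing.assert_allclose(m.nodal_efficiency(P3), [0.75, 1.0, 0.75])

    @pytest.mark.parametrize(
        "W, expected",
        [
            (P3, [0, 1, 0]),
            (K3, [0, 0, 0]),
            (C4, [1.0 / 6.0] * 4),  # two tied shortest paths split credit
        ],
    )
    def test_betweenness(self, W, expected):
        np.testing.assert_allclose(m.betweenness_centrality(W), expected)


class TestAnalyticIdentities:
    def test_mean_nodal_equals_global_efficiency(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            W = oracles.random_connected_weighted_graph(rng)
            assert np.mean(m.nodal_efficiency(W)) == pytest.approx(
                m.global_efficiency(W), abs=1e-12
            )

    def test_sigma_is_gamma_over_lambda_and_self_ensemble_identity(self):
        rng = np.random.default_rng(1)
        W = oracles.random_connected_weighted_graph(rng, n_max=7)
        gamma, lam, sigma = m.small_worldness(W, [Connectome(W)])
        assert gamma == pytest.approx(1.0)
        assert lam == pytest.approx(1.0)
        assert sigma == pytest.approx(gamma / lam)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_all_metrics_match_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        W = oracles.random_connected_weighted_graph(rng)
        np.testing.assert_allclose(
            m.shortest_paths(W), oracles.brute_distance_matrix(W), atol=1e-9
        )
        assert m.global_efficiency(W) == pytest.approx(
            oracles.brute_global_efficiency(W), abs=1e-9
        )
        np.testing.assert_allclose(
            m.nodal_efficiency(W), oracles.brute_nodal_efficiency(W), atol=1e-9
        )
        assert m.characteristic_path_length(W) == pytest.approx(
            oracles.brute_path_length(W), abs=1e-9
        )
        np.testing.assert_allclose(
            m.nodal_local_efficiency(W),
            oracles.brute_local_efficiency_vector(W),
            atol=1e-9,
        )
        np.testing.assert_allclose(
            m.clustering_coefficient(W)[1], oracles.brute_clustering(W), atol=1e-9
        )
        np.testing.assert_allclose(
            m.betweenness_centrality(W), oracles.brute_betweenness(W), atol=1e-9
        )


class TestScaleBehavior:
    def test_weight_rescaling(self):
        rng = np.random.default_rng(2)
        W = oracles.random_connected_weighted_graph(rng)
        c = 3.7
        assert m.global_efficiency(c * W) == pytest.approx(c * m.global_efficiency(W))
        np.testing.assert_allclose(m.degree_strength(c * W), c * m.degree_strength(W))
        assert m.characteristic_path_length(c * W) == pytest.approx(
            m.characteristic_path_length(W) / c
        )
        np.testing.assert_allclose(
            m.clustering_coefficient(c * W)[1], m.clustering_coefficient(W)[1]
        )
        np.testing.assert_allclose(
            m.betweenness_centrality(c * W), m.betweenness_centrality(W)
        )

    def test_adding_edge_never_decreases_efficiency(self):
        rng = np.random.default_rng(3)
        W = oracles.random_connected_weighted_graph(rng)
        base = m.global_efficiency(W)
        iu, ju = np.where(np.triu(W, 1) == 0)
        off = [(a, b) for a, b in zip(iu, ju)]
        if off:
            a, b = off[0]
            W2 = W.copy()
            W2[a, b] = W2[b, a] = 0.5
            assert m.global_efficiency(W2) >= base - 1e-12


class TestRandomEnsemble:
    def test_construction_invariants_and_determinism(self):
        rng = np.random.default_rng(4)
        W = oracles.random_connected_weighted_graph(rng, n_max=7)
        ens1 = m.random_ensemble(W, n=5, seed=9)
        ens2 = m.random_ensemble(W, n=5, seed=9)
        deg = np.sort((W > 0).sum(axis=1))
        wts = np.sort(W[W > 0])
        for g1, g2 in zip(ens1, ens2):
            np.testing.assert_array_equal(g1.weights, g2.weights)  # bitwise
            np.testing.assert_array_equal(np.sort((g1.weights > 0).sum(axis=1)), deg)
            np.testing.assert_allclose(np.sort(g1.weights[g1.weights > 0]), wts)

    def test_too_few_edges_rejected(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        with pytest.raises(ValueError, match="2 edges"):
            m.random_ensemble(W, n=2, seed=0)
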