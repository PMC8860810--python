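"""Network estimation: glasso path, EBIC selection, conversions."""

import numpy as np
import pytest

from symptomnet import (
    NetworkConfig,
    correlation_matrix,
    ebic,
    estimate_network,
    generate_dataset,
    glasso_path,
    lambda_grid,
    paper_topology_spec,
    precision_to_pcor,
    random_sparse_spec,
    select_network,
)
from symptomnet.estimation import EDGE_TOL, EstimationError, PathFit
from symptomnet.synthesize import implied_correlation

from conftest import chain_spec
from oracles import pcor_by_inversion


class TestPrecisionToPcor:
    def test_tridiagonal_hand_computation(self):
        K = np.array([[2.0, -1.0, 0.0], [-1.0, 2.0, -1.0], [0.0, -1.0, 2.0]])
        P = precision_to_pcor(K)
        assert P[0, 1] == pytest.approx(0.5)
        assert P[0, 2] == pytest.approx(0.0)
        assert P[1, 2] == pytest.approx(0.5)

    def test_identity_and_negative_entry(self):
        np.testing.assert_allclose(precision_to_pcor(np.eye(4)), np.eye(4))
        P = precision_to_pcor(np.array([[4.0, 2.0], [2.0, 4.0]]))
        assert P[0, 1] == pytest.approx(-0.5)

    def test_non_pd_rejected(self):
        with pytest.raises(EstimationError, match="positive definite"):
            precision_to_pcor(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestEbic:
    def test_no_edges_means_no_penalty(self):
        for gamma in (0.0, 0.5, 1.0):
            assert ebic(-150.0, 0, 100, 16, gamma) == pytest.approx(300.0)

    def test_gamma_zero_reduces_to_bic(self):
        assert ebic(-10.0, 4, 50, 8, 0.0) == pytest.approx(20.0 + 4 * np.log(50))

    def test_arithmetic_example(self):
        # 300 + 3 log 100 + 6 log 16
        assert ebic(-150.0, 3, 100, 16, 0.5) == pytest.approx(330.451, abs=1e-3)

    def test_negative_edge_count_rejected(self):
        with pytest.raises(EstimationError):
            ebic(-1.0, -1, 10, 4, 0.5)


class TestCorrelationMatrix:
    def test_duplicate_columns_correlate_perfectly(self):
        x = np.random.default_rng(0).normal(size=50)
        S = correlation_matrix(np.column_stack([x, x, -x]))
        assert S.S[0, 1] == pytest.approx(1.0)
        assert S.S[0, 2] == pytest.approx(-1.0)

    def test_independent_data_nearly_diagonal(self):
        data = generate_dataset(chain_spec({}, 4, n_subjects=5000, seed=2))
        S = correlation_matrix(data)
        off = S.S[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05
        assert not S.repaired

    def test_constant_column_rejected(self):
        X = np.ones((30, 3))
        X[:, 0] = np.arange(30)
        X[:, 2] = np.arange(30) ** 2
        with pytest.raises(EstimationError, match="zero-variance"):
            correlation_matrix(X)

    def test_tiny_sample_rejected(self):
        with pytest.raises(EstimationError, match="insufficient"):
            correlation_matrix(np.random.default_rng(1).normal(size=(2, 4)))

    def test_spearman_option(self):
        data = generate_dataset(chain_spec({(0, 1): 0.4}, 3, n_subjects=400, seed=8))
        S = correlation_matrix(data, method="spearman")
        assert S.method == "spearman"
        assert abs(S.S[0, 1]) > 0.1


class TestLambdaGrid:
    def test_log_spacing_closed_form(self):
        S = np.eye(3)
        S[0, 1] = S[1, 0] = 0.6
        grid = lambda_grid(S, n_lambda=100, min_ratio=0.01)
        assert grid.lambdas[0] == pytest.approx(0.6)
        assert grid.lambdas[-1] == pytest.approx(0.006)
        ratios = grid.lambdas[1:] / grid.lambdas[:-1]
        np.testing.assert_allclose(ratios, ratios[0])

    def test_two_point_grid(self):
        S = np.eye(2)
        S[0, 1] = S[1, 0] = 0.4
        grid = lambda_grid(S, n_lambda=2, min_ratio=0.5)
        np.testing.assert_allclose(grid.lambdas, [0.4, 0.2])

    def test_identity_has_no_model(self):
        with pytest.raises(EstimationError, match="empty model"):
            lambda_grid(np.eye(4))


class TestGlassoPath:
    def test_empty_graph_at_lambda_max(self):
        data = generate_dataset(chain_spec({(0, 1): 0.3, (1, 2): 0.3}, 4, seed=3))
        S = correlation_matrix(data)
        fit = glasso_path(S, lambda_grid(S, n_lambda=10, min_ratio=0.1))
        assert fit.edge_counts[0] == 0
        off = fit.precisions[0][~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 1e-8

    def test_unpenalized_limit_matches_direct_inversion(self):
        spec = random_sparse_spec(n_nodes=6, n_edges=5, seed=0, n_subjects=1000)
        S_true = implied_correlation(spec.true_partial_corr)
        from symptomnet.estimation import CorrelationMatrix, LambdaPath

        S = CorrelationMatrix(S=S_true, method="pearson", n=1000)
        fit = glasso_path(S, LambdaPath(lambdas=np.array([1e-6])))
        np.testing.assert_allclose(fit.pcors[0], pcor_by_inversion(S_true), atol=1e-4)

    def test_edge_count_monotone_on_fixture(self):
        data = generate_dataset(
            chain_spec({(0, 1): 0.35, (1, 2): 0.3, (2, 3): 0.3, (3, 4): 0.25}, 5, seed=6)
        )
        S = correlation_matrix(data)
        fit = glasso_path(S, lambda_grid(S, n_lambda=40, min_ratio=0.01))
        assert (np.diff(fit.edge_counts) >= 0).all()  # lambdas decrease along path

    def test_pcor_symmetry_and_bounds_along_path(self):
        data = generate_dataset(chain_spec({(0, 1): 0.4, (2, 3): -0.3}, 4, seed=4))
        S = correlation_matrix(data)
        fit = glasso_path(S, lambda_grid(S, n_lambda=15, min_ratio=0.05))
        for W in fit.pcors:
            np.testing.assert_allclose(W, W.T, atol=1e-10)
            off = W[~np.eye(4, dtype=bool)]
            assert np.max(np.abs(off)) < 1.0


class TestSelection:
    @staticmethod
    def _toy_fit(ebic_shape):
        # hand-built path: logliks tuned so EBIC at gamma=0 equals ebic_shape
        lambdas = np.geomspace(1.0, 0.01, len(ebic_shape))
        logliks = np.array([-(v + 0) / 2.0 for v in ebic_shape])
        return PathFit(
            lambdas=lambdas,
            precisions=[np.eye(3)] * len(ebic_shape),
            pcors=[np.eye(3)] * len(ebic_shape),
            edge_counts=np.zeros(len(ebic_shape), dtype=int),
            logliks=logliks,
            n=100,
            p=3,
        )

    def test_unique_minimum_selected(self):
        fit = self._toy_fit([10.0, 8.0, 5.0, 9.0])
        net = select_network(fit, gamma=0.0)
        assert net.lambda_selected == pytest.approx(fit.lambdas[2])

    def test_tie_broken_toward_larger_lambda(self):
        fit = self._toy_fit([9.0, 5.0, 5.0, 7.0])
        net = select_network(fit, gamma=0.0)
        assert net.lambda_selected == pytest.approx(fit.lambdas[1])

    def test_gamma_half_never_denser_than_bic(self):
        for seed in range(20):
            spec = random_sparse_spec(n_nodes=10, n_edges=8, seed=seed, n_subjects=300)
            data = generate_dataset(spec)
            S = correlation_matrix(data)
            fit = glasso_path(S, lambda_grid(S, n_lambda=40, min_ratio=0.05))
            sparse = select_network(fit, gamma=0.5)
            dense = select_network(fit, gamma=0.0)
            assert sparse.n_edges <= dense.n_edges


class TestEstimateNetwork:
    def test_planted_bridge_edge_recovered(self):
        data = generate_dataset(paper_topology_spec("BN", n_subjects=2000, seed=1))
        net = estimate_network(data)
        i = net.node_names.index("emotional_abuse")
        j = net.node_names.index("ineffectiveness")
        assert net.W[i, j] > 0.1

    def test_deterministic(self):
        data = generate_dataset(chain_spec({(0, 1): 0.4}, 4, seed=12))
        a = estimate_network(data)
        b = estimate_network(data)
        np.testing.assert_array_equal(a.W, b.W)
        assert a.lambda_selected == b.lambda_selected

    def test_more_variables_than_subjects_is_feasible(self):
        spec = paper_topology_spec("BN", n_subjects=5, seed=3)
        net = estimate_network(generate_dataset(spec))
        assert net.p == 16
        np.testing.assert_allclose(net.W, net.W.T, atol=1e-10)

    def test_network_invariants(self):
        data = generate_dataset(chain_spec({(0, 1): 0.4, (1, 2): 0.3}, 5, seed=13))
        net = estimate_network(data)
        assert np.all(np.diag(net.W) == 0)
        np.testing.assert_allclose(net.W, net.W.T, atol=1e-10)
        assert np.max(np.abs(net.W)) < 1.0
        assert net.metadata["edge_count"] == net.n_edges

    def test_refit_preserves_support_and_strengthens_weights(self):
        data = generate_dataset(chain_spec({(0, 1): 0.4, (1, 2): 0.35}, 4, n_subjects=800, seed=14))
        base = estimate_network(data, NetworkConfig())
        refit = estimate_network(data, NetworkConfig(refit=True))
        support = np.abs(base.W) > EDGE_TOL
        assert ((np.abs(refit.W) > EDGE_TOL) == support).all()
        # shrinkage removed: selected edges move away from zero on average
        assert np.abs(refit.W[support]).mean() >= np.abs(base.W[support]).mean()
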