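"""Estimator contracts: closed forms, reductions, monotonicity, recovery."""

import numpy as np
import pytest

import fbn
from fbn.errors import ContractError, ParameterError
from fbn.estimators import (
    SolverConfig,
    estimate_pc_scale_free,
    estimate_pc_sparsity,
    estimate_sr,
    gamma_weights,
    hard_threshold_network,
    pearson_network,
    scale_free_objective,
    soft_threshold,
    weighted_soft_threshold,
)
from fbn.graph_metrics import edge_count
from fbn.preprocess import standardize_columns


def centered_orthonormal_columns(t, n, rng):
    """Columns that are exactly centered and orthonormal (QR of a centered
    matrix stays in the centered subspace)."""
    A = rng.standard_normal((t, n))
    A -= A.mean(axis=0, keepdims=True)
    Q, _ = np.linalg.qr(A)
    return standardize_columns(Q[:, :n])


class TestPearson:
    def test_identical_and_negated_columns(self):
        x = np.arange(10.0)
        Xs = standardize_columns(np.column_stack([x, x, -x]))
        W = pearson_network(Xs).W
        assert W[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert W[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_quotient_double_loop(self, rng):
        X = rng.standard_normal((30, 5))
        W = pearson_network(standardize_columns(X)).W
        for i in range(5):
            for j in range(5):
                xc = X[:, i] - X[:, i].mean()
                yc = X[:, j] - X[:, j].mean()
                r = xc @ yc / np.sqrt((xc @ xc) * (yc @ yc))
                assert abs(W[i, j] - r) < 1e-12

    def test_rejects_non_standardized(self, rng):
        with pytest.raises(ContractError):
            pearson_network(rng.standard_normal((20, 4)) + 5.0)


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "w,tau,expected",
        [(0.0, 0.7, 0.0), (0.9, 0.3, 0.6), (-0.9, 0.3, -0.6), (-0.2, 0.5, 0.0)],
    )
    def test_scalar_cases(self, w, tau, expected):
        assert soft_threshold(np.array([[w]]), tau)[0, 0] == pytest.approx(expected)

    def test_negative_tau_rejected(self):
        with pytest.raises(ParameterError):
            soft_threshold(np.zeros((2, 2)), -0.1)

    def test_weighted_reduces_to_plain_with_unit_gamma(self, rng):
        W = rng.standard_normal((6, 6))
        np.testing.assert_array_equal(
            weighted_soft_threshold(W, 0.3, np.ones_like(W)),
            soft_threshold(W, 0.3),
        )

    def test_zero_gamma_passes_unshrunk(self, rng):
        W = rng.standard_normal((4, 4))
        np.testing.assert_array_equal(
            weighted_soft_threshold(W, 5.0, np.zeros_like(W)), W
        )

    def test_weighted_matches_scalar_double_loop(self, rng):
        W = rng.standard_normal((7, 7))
        G = rng.uniform(0, 2, size=(7, 7))
        out = weighted_soft_threshold(W, 0.4, G)
        for i in range(7):
            for j in range(7):
                expected = np.sign(W[i, j]) * max(abs(W[i, j]) - 0.4 * G[i, j], 0.0)
                assert abs(out[i, j] - expected) < 1e-15


class TestHardThreshold:
    def test_full_sparsity_keeps_everything(self, std_small):
        W = pearson_network(std_small)
        out = hard_threshold_network(W, 100.0)
        off = ~np.eye(W.n, dtype=bool)
        np.testing.assert_allclose(out.W[off], W.W[off], atol=1e-15)

    def test_keeps_strongest_pair(self):
        W = np.array(
            [[0.0, 0.9, 0.1], [0.9, 0.0, -0.5], [0.1, -0.5, 0.0]]
        )
        out = hard_threshold_network(W, 100.0 / 3.0).W  # k = 1 pair
        assert out[0, 1] == 0.9 and out[1, 0] == 0.9
        assert out[0, 2] == 0.0 and out[1, 2] == 0.0

    def test_absolute_ranking_keeps_negative_edges(self):
        W = np.array([[0.0, -0.9, 0.1], [-0.9, 0.0, 0.2], [0.1, 0.2, 0.0]])
        out = hard_threshold_network(W, 100.0 / 3.0).W
        assert out[0, 1] == -0.9
        signed = hard_threshold_network(W, 100.0 / 3.0, ranking="signed").W
        assert signed[0, 1] == 0.0 and signed[1, 2] == 0.2

    def test_support_nesting_in_sparsity_level(self, rng):
        W = rng.standard_normal((10, 10))
        W = (W + W.T) / 2
        sup = {}
        for p in (20.0, 50.0, 80.0):
            out = hard_threshold_network(W, p).W
            sup[p] = set(zip(*np.nonzero(np.triu(out, k=1))))
        assert sup[20.0] <= sup[50.0] <= sup[80.0]

    def test_invalid_percent_rejected(self):
        with pytest.raises(ParameterError):
            hard_threshold_network(np.zeros((3, 3)), 0.0)


class TestPcSparsity:
    def test_lambda_zero_recovers_pearson(self, std_small):
        W = estimate_pc_sparsity(std_small, SolverConfig(lam=0.0))
        np.testing.assert_array_equal(W.W, pearson_network(std_small).W)
        assert W.converged

    def test_matches_closed_form(self, std_medium):
        S = pearson_network(std_medium).W
        out = estimate_pc_sparsity(std_medium, SolverConfig(lam=0.4))
        np.testing.assert_allclose(out.W, soft_threshold(S, 0.2), atol=1e-8)

    def test_large_lambda_empties_offdiagonal(self, std_small):
        S = pearson_network(std_small).W
        off = ~np.eye(S.shape[0], dtype=bool)
        lam = 2.0 * np.abs(S[off]).max() + 0.01
        out = estimate_pc_sparsity(std_small, SolverConfig(lam=lam))
        np.testing.assert_array_equal(out.W[off], 0.0)

    def test_sparsity_monotone_in_lambda(self, std_medium):
        counts = [
            edge_count(estimate_pc_sparsity(std_medium, SolverConfig(lam=lam)))
            for lam in np.arange(0.05, 1.01, 0.05)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_symmetry(self, std_medium):
        W = estimate_pc_sparsity(std_medium, SolverConfig(lam=0.3)).W
        assert np.max(np.abs(W - W.T)) <= 1e-10

    def test_legacy_prox_uses_full_lambda(self, std_small):
        S = pearson_network(std_small).W
        out = estimate_pc_sparsity(
            std_small, SolverConfig(lam=0.4, legacy_prox=True)
        )
        np.testing.assert_allclose(out.W, soft_threshold(S, 0.4), atol=1e-6)

    def test_support_recovery_on_long_series(self):
        """At t ≫ n and an oracle λ between noise floor and signal floor,
        the shrunk correlation support recovers the true edge set (F1 ≥ 0.9)."""
        net = fbn.make_ground_truth(
            n=20, topology="random_sparse", density=0.15, seed=3
        )
        ts = fbn.simulate_timeseries(net, t=4000, noise_sd=0.05, seed=4)
        Xs = standardize_columns(ts)
        pop = fbn.population_correlation(net, noise_sd=0.05)
        iu, ju = np.triu_indices(20, k=1)
        true_edges = np.abs(net.W_true[iu, ju]) > 0
        signal_floor = np.abs(pop[iu, ju][true_edges]).min()
        out = estimate_pc_sparsity(Xs, SolverConfig(lam=signal_floor))
        found = np.abs(out.W[iu, ju]) > 1e-12
        tp = np.sum(found & true_edges)
        f1 = 2 * tp / (found.sum() + true_edges.sum())
        assert f1 >= 0.9


class TestGammaWeights:
    def test_isolated_nodes_underflow_to_zero(self):
        G = gamma_weights(np.zeros((4, 4)), epsilon=1e-4).Gamma
        np.testing.assert_array_equal(G, 0.0)

    def test_monotone_increasing_in_degree(self):
        """γ at equal degrees d equals e^(−2/(d+ε)) and increases with d."""
        eps = 1e-4
        vals = []
        for d in [0.5, 1.0, 2.0, 5.0, 20.0]:
            W = np.array([[0.0, d / 2, d / 2, 0], [d / 2, 0, 0, d / 2],
                          [d / 2, 0, 0, d / 2], [0, d / 2, d / 2, 0.0]])
            G = gamma_weights(W, eps).Gamma
            assert G[0, 1] == pytest.approx(np.exp(-2.0 / (d + eps)), rel=1e-12)
            vals.append(G[0, 1])
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_scalar_evaluation(self):
        W = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 2.0], [0.0, 2.0, 0.0]])
        G = gamma_weights(W, 1e-4).Gamma  # d = (1, 3, 2)
        expected = np.exp(-(1 / 1.0001 + 1 / 3.0001))
        assert G[0, 1] == pytest.approx(expected, rel=1e-12)
        np.testing.assert_allclose(G, G.T)

    def test_diagonal_excluded_from_degree(self):
        W = np.eye(3) * 5.0
        np.testing.assert_array_equal(gamma_weights(W, 1e-4).Gamma, 0.0)

    def test_inverse_mode_is_complement(self, rng):
        W = rng.standard_normal((5, 5))
        direct = gamma_weights(W, 1e-4, mode="direct").Gamma
        inverse = gamma_weights(W, 1e-4, mode="inverse").Gamma
        np.testing.assert_allclose(inverse, 1.0 - direct, atol=1e-15)


class TestPcScaleFree:
    def test_lambda_zero_recovers_pearson(self, std_small):
        out = estimate_pc_scale_free(std_small, SolverConfig(lam=0.0))
        np.testing.assert_array_equal(out.W, pearson_network(std_small).W)
        assert out.converged

    def test_single_outer_iteration_equals_pc_sparsity(self, std_medium):
        """With Γ frozen at all-ones (first W-update only) the weighted
        estimator coincides with the plain L1 one."""
        sparse = estimate_pc_sparsity(std_medium, SolverConfig(lam=0.4))
        with pytest.warns(RuntimeWarning):  # only one outer iteration allowed
            one_step = estimate_pc_scale_free(
                std_medium, SolverConfig(lam=0.4, outer_max_iter=1)
            )
        np.testing.assert_allclose(one_step.W, sparse.W, atol=1e-8)

    def test_objective_non_increasing_across_w_updates(self, std_medium):
        """Each W-update is an exact argmin for the current Γ, so the
        penalized objective at fixed Γ cannot rise across it."""
        S = pearson_network(std_medium).W
        Gamma = np.ones_like(S)
        W = S.copy()
        for _ in range(10):
            obj_before = scale_free_objective(W, S, 0.3, Gamma)
            W_new = weighted_soft_threshold(S, 0.15, Gamma)
            obj_after = scale_free_objective(W_new, S, 0.3, Gamma)
            assert obj_after <= obj_before + 1e-10
            Gamma = gamma_weights(W_new, 1e-4).Gamma
            W = W_new

    def test_symmetry(self, std_medium):
        W = estimate_pc_scale_free(std_medium, SolverConfig(lam=0.3)).W
        assert np.max(np.abs(W - W.T)) <= 1e-10

    def test_nonconvergent_cycle_flagged(self):
        """On hub-structured data at moderate λ the γ alternation 2-cycles;
        the last iterate must be returned with converged=False."""
        net = fbn.make_ground_truth(n=60, topology="hub", density=0.05,
                                    hub_count=5, seed=9)
        ts = fbn.simulate_timeseries(net, t=170, noise_sd=0.2, seed=10)
        Xs = standardize_columns(ts)
        with pytest.warns(RuntimeWarning, match="did not settle"):
            out = estimate_pc_scale_free(Xs, SolverConfig(lam=0.5))
        assert not out.converged
        assert out.iterations == SolverConfig().outer_max_iter


class TestSparseRepresentation:
    def test_orthogonal_columns_give_zero(self, rng):
        Xs = centered_orthonormal_columns(30, 5, rng)
        out = estimate_sr(Xs, SolverConfig(lam=0.1))
        np.testing.assert_allclose(out.W, 0.0, atol=1e-10)

    def test_objective_monotone(self, rng):
        Xs = standardize_columns(rng.standard_normal((30, 10)))
        out = estimate_sr(Xs, SolverConfig(lam=0.1))
        diffs = np.diff(out.objective_history)
        assert np.all(diffs <= 1e-10)
        assert out.converged

    def test_duplicate_column_matches_scalar_lasso(self):
        """x₂ = x₁ decouples into scalar lasso problems whose closed form
        is soft(1, λ/2)."""
        x = np.sin(np.arange(40.0))
        Xs = standardize_columns(np.column_stack([x, x]))
        lam = 0.3
        out = estimate_sr(Xs, SolverConfig(lam=lam, tol=1e-12, max_iter=5000))
        expected = max(1.0 - lam / 2.0, 0.0)
        assert out.W[0, 1] == pytest.approx(expected, abs=1e-8)
        assert out.W[1, 0] == pytest.approx(expected, abs=1e-8)

    def test_diagonal_zero_and_symmetrized(self, rng):
        Xs = standardize_columns(rng.standard_normal((25, 8)))
        out = estimate_sr(Xs, SolverConfig(lam=0.05))
        np.testing.assert_array_equal(np.diag(out.W), 0.0)
        assert np.max(np.abs(out.W - out.W.T)) <= 1e-12
        raw = estimate_sr(Xs, SolverConfig(lam=0.05), symmetrize=False)
        np.testing.assert_array_equal(np.diag(raw.W), 0.0)


def test_solver_config_validation():
    with pytest.raises(ParameterError):
        SolverConfig(step_alpha=0.0)
    with pytest.raises(ParameterError):
        SolverConfig(lam=-0.1)
    with pytest.raises(ParameterError):
        SolverConfig(tol=0.0)
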