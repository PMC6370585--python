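import numpy as np
import pytest

from nrlmfb.nrlmf_core import (
    Hyperparameters,
    build_neighborhood_graph,
    fit,
    gradients,
    interaction_probability,
    objective,
    score,
    smooth_negatives,
)
from nrlmfb.synthetic_data import generate
from nrlmfb.evaluation import auc

HP_SMALL = Hyperparameters(c=5.0, K1=2, K2=2, r=2, lambda_d=0.1, lambda_t=0.2,
                           alpha=0.3, beta=0.4, theta=0.5, max_iter=20)


class TestHyperparameters:
    @pytest.mark.parametrize("bad", [dict(c=0.0), dict(lambda_d=-1.0), dict(K1=0),
                                     dict(eta2=2.0), dict(theta=0.0), dict(r=0)])
    def test_validation(self, bad):
        with pytest.raises(ValueError):
            Hyperparameters(**bad)

    def test_from_mapping_rejects_unknown_keys(self):
        with pytest.raises(ValueError, match="gamma"):
            Hyperparameters.from_mapping({"c": 5.0, "gamma": 1.0})


class TestInteractionProbability:
    def test_logistic_closed_forms(self):
        U = np.array([[0.0], [np.log(3.0)]])
        V = np.array([[1.0]])
        P = interaction_probability(U, V)
        assert P[0, 0] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.75)

    def test_extreme_logits_are_finite(self):
        P = interaction_probability(np.array([[-800.0], [800.0]]), np.array([[1.0]]))
        assert np.isfinite(P).all()
        assert P[1, 0] <= 1.0

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            interaction_probability(np.array([[np.nan]]), np.array([[1.0]]))


class TestNeighborhoodGraph:
    def test_identity_similarity_gives_zero_laplacian(self):
        g = build_neighborhood_graph(np.eye(3), K1=1)
        np.testing.assert_array_equal(g.L, np.zeros((3, 3)))

    def test_two_node_unit_edge(self):
        S = np.array([[1.0, 1.0], [1.0, 1.0]])
        g = build_neighborhood_graph(S, K1=1)
        np.testing.assert_allclose(g.L, np.array([[2.0, -2.0], [-2.0, 2.0]]))

    def test_k1_bounds(self):
        with pytest.raises(ValueError):
            build_neighborhood_graph(np.eye(3), K1=3)

    def test_row_sparsity_and_zero_diagonal(self, rng):
        S = rng.random((7, 7))
        np.fill_diagonal(S, 1.0)
        g = build_neighborhood_graph(S, K1=3)
        assert (np.count_nonzero(g.A, axis=1) <= 3).all()
        assert np.diag(g.A).sum() == 0.0
        np.testing.assert_allclose(g.L.sum(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(g.L, g.L.T)

    def test_quadratic_form_equals_pairwise_sum(self, rng):
        """x'Lx must equal the weighted sum of squared neighbor distances."""
        S = rng.random((6, 6))
        np.fill_diagonal(S, 1.0)
        g = build_neighborhood_graph(S, K1=2)
        for _ in range(20):
            x = rng.standard_normal((6, 3))
            quad = np.trace(x.T @ g.L @ x)
            brute = sum(
                g.A[i, l] * np.sum((x[i] - x[l]) ** 2)
                for i in range(6)
                for l in range(6)
            )
            assert quad == pytest.approx(brute, rel=1e-10)


def brute_objective(U, V, Y, Ld, Lt, hp):
    """Naive double-loop evaluation of the MAP objective."""
    total = 0.0
    nd, nt = Y.shape
    for i in range(nd):
        for j in range(nt):
            z = float(U[i] @ V[j])
            y = Y[i, j]
            total += (1 + hp.c * y - y) * np.log1p(np.exp(z)) - hp.c * y * z
    total += 0.5 * np.trace(U.T @ (hp.lambda_d * np.eye(nd) + hp.alpha * Ld) @ U)
    total += 0.5 * np.trace(V.T @ (hp.lambda_t * np.eye(nt) + hp.beta * Lt) @ V)
    return total


class TestObjectiveAndGradients:
    def test_zero_latents_closed_form(self, rng):
        Y = (rng.random((4, 3)) < 0.4).astype(float)
        hp = HP_SMALL
        U, V = np.zeros((4, 2)), np.zeros((3, 2))
        val = objective(U, V, Y, np.zeros((4, 4)), np.zeros((3, 3)), hp)
        expected = np.sum(1 + hp.c * Y - Y) * np.log(2.0)
        assert val == pytest.approx(expected)

    def test_single_term_reduction(self):
        hp = Hyperparameters(c=5.0, K1=1, K2=1, r=1, lambda_d=1e-12, lambda_t=1e-12,
                             alpha=1e-12, beta=1e-12, max_iter=1)
        t = 1.7
        val = objective(np.array([[t]]), np.array([[1.0]]), np.zeros((1, 1)),
                        np.zeros((1, 1)), np.zeros((1, 1)), hp)
        assert val == pytest.approx(np.log1p(np.exp(t)), rel=1e-9)

    def test_objective_matches_brute_force(self, rng):
        Y = (rng.random((5, 4)) < 0.3).astype(float)
        U = rng.standard_normal((5, 2))
        V = rng.standard_normal((4, 2))
        Ld = _random_laplacian(rng, 5)
        Lt = _random_laplacian(rng, 4)
        val = objective(U, V, Y, Ld, Lt, HP_SMALL)
        assert val == pytest.approx(brute_objective(U, V, Y, Ld, Lt, HP_SMALL), rel=1e-10)

    def test_gradient_zero_at_origin_without_interactions(self):
        U, V = np.zeros((3, 2)), np.zeros((2, 2))
        gU, gV = gradients(U, V, np.zeros((3, 2)), np.zeros((3, 3)), np.zeros((2, 2)),
                           HP_SMALL)
        np.testing.assert_array_equal(gU, 0.0)
        np.testing.assert_array_equal(gV, 0.0)

    def test_gradient_matches_finite_differences(self, rng):
        Y = (rng.random((4, 3)) < 0.4).astype(float)
        U = 0.3 * rng.standard_normal((4, 2))
        V = 0.3 * rng.standard_normal((3, 2))
        Ld = _random_laplacian(rng, 4)
        Lt = _random_laplacian(rng, 3)
        gU, gV = gradients(U, V, Y, Ld, Lt, HP_SMALL)
        eps = 1e-6

        def num_grad(M, which):
            G = np.zeros_like(M)
            for idx in np.ndindex(M.shape):
                Mp, Mm = M.copy(), M.copy()
                Mp[idx] += eps
                Mm[idx] -= eps
                if which == "U":
                    G[idx] = (objective(Mp, V, Y, Ld, Lt, HP_SMALL)
                              - objective(Mm, V, Y, Ld, Lt, HP_SMALL)) / (2 * eps)
                else:
                    G[idx] = (objective(U, Mp, Y, Ld, Lt, HP_SMALL)
                              - objective(U, Mm, Y, Ld, Lt, HP_SMALL)) / (2 * eps)
            return G

        np.testing.assert_allclose(gU, num_grad(U, "U"), rtol=1e-5, atol=1e-7)
        np.testing.assert_allclose(gV, num_grad(V, "V"), rtol=1e-5, atol=1e-7)

    def test_all_ones_simplification(self, rng):
        """With no regularization and Y all ones the U-gradient is c(P-1)V."""
        Y = np.ones((3, 2))
        hp = Hyperparameters(c=4.0, K1=1, K2=1, r=2, lambda_d=1e-300, lambda_t=1e-300,
                             alpha=1e-300, beta=1e-300, max_iter=1)
        U = rng.standard_normal((3, 2))
        V = rng.standard_normal((2, 2))
        gU, _ = gradients(U, V, Y, np.zeros((3, 3)), np.zeros((2, 2)), hp)
        P = interaction_probability(U, V)
        np.testing.assert_allclose(gU, (hp.c * (P - 1)) @ V, rtol=1e-10, atol=1e-12)


def _random_laplacian(rng, n):
    W = rng.random((n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    return np.diag(W.sum(axis=1)) - W


class TestSmoothNegatives:
    def test_positive_rows_unchanged(self, rng):
        X = rng.standard_normal((4, 2))
        S = rng.random((4, 4))
        out = smooth_negatives(X, S, K2=2, positive_mask=np.ones(4, bool))
        np.testing.assert_array_equal(out, X)

    def test_single_perfect_neighbor(self):
        X = np.arange(8.0).reshape(4, 2)
        S = np.zeros((4, 4))
        S[3, 0] = 1.0
        mask = np.array([True, True, True, False])
        out = smooth_negatives(X, S, K2=1, positive_mask=mask)
        np.testing.assert_array_equal(out[3], X[0])

    def test_weighted_average_hand_case(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [5.0, 5.0], [0.0, 0.0]])
        S = np.zeros((4, 4))
        S[3, 0], S[3, 1], S[3, 2] = 0.8, 0.2, 0.05
        mask = np.array([True, True, True, False])
        out = smooth_negatives(X, S, K2=2, positive_mask=mask)
        np.testing.assert_allclose(out[3], (0.8 * X[0] + 0.2 * X[1]) / 1.0)

    def test_no_positives_is_error(self):
        with pytest.raises(ValueError):
            smooth_negatives(np.zeros((3, 2)), np.eye(3), 1, np.zeros(3, bool))

    def test_zero_similarity_keeps_row_with_warning(self):
        X = np.ones((3, 2))
        X[2] = 7.0
        S = np.zeros((3, 3))
        mask = np.array([True, True, False])
        with pytest.warns(RuntimeWarning):
            out = smooth_negatives(X, S, K2=2, positive_mask=mask)
        np.testing.assert_array_equal(out[2], X[2])


class TestFit:
    def test_determinism(self):
        ds = generate(12, 8, 2, 0.2, seed=3).dataset
        hp = Hyperparameters(r=2, K1=3, K2=3, max_iter=30)
        a = fit(ds, hp, seed=11)
        b = fit(ds, hp, seed=11)
        np.testing.assert_array_equal(a.U, b.U)
        np.testing.assert_array_equal(a.V, b.V)

    def test_objective_trace_decreases_overall(self):
        ds = generate(15, 10, 3, 0.15, seed=1).dataset
        model = fit(ds, Hyperparameters(r=3, max_iter=50), seed=0)
        assert model.objective_trace[-1] <= model.objective_trace[0]
        steps = np.diff(model.objective_trace)
        assert np.median(steps) < 0  # AdaGrad is not per-step monotone

    def test_recovers_planted_structure_in_training(self):
        syn = generate(30, 20, 3, 0.15, seed=9)
        model = fit(syn.dataset, Hyperparameters(r=3, alpha=1.0, beta=1.0), seed=2)
        s = score(model)
        assert auc(syn.dataset.Y.ravel(), s.ravel()) > 0.9

    def test_smoothing_identity_without_negatives(self):
        # every drug and target interacts at least once
        syn = generate(10, 6, 2, 0.45, seed=21)
        Y = syn.dataset.Y.copy()
        Y[Y.sum(axis=1) == 0, 0] = 1.0
        Y[0, Y.sum(axis=0) == 0] = 1.0
        ds = syn.dataset.with_adjacency(Y)
        model = fit(ds, Hyperparameters(r=2, K1=3, K2=3, max_iter=20), seed=0)
        np.testing.assert_array_equal(model.U, model.U_smoothed)
        np.testing.assert_array_equal(model.V, model.V_smoothed)
        np.testing.assert_allclose(
            score(model), interaction_probability(model.U, model.V)
        )

    def test_prior_shrinks_latents(self):
        """Without interactions or Laplacian terms, the fitted norm of U
        decreases monotonically as the prior precision lambda_d grows."""
        ds = generate(10, 8, 2, 0.2, seed=4).dataset.with_adjacency(np.zeros((10, 8)))
        norms = []
        for lam in (0.01, 1.0, 100.0):
            hp = Hyperparameters(r=2, lambda_d=lam, lambda_t=lam,
                                 alpha=1e-300, beta=1e-300, max_iter=60)
            model = fit(ds, hp, seed=5)
            norms.append(np.linalg.norm(model.U))
        assert norms[0] > norms[1] > norms[2]

    def test_divergent_rate_raises(self):
        ds = generate(8, 6, 2, 0.2, seed=2).dataset
        hp = Hyperparameters(r=2, theta=1e200, max_iter=20)
        with pytest.raises(FloatingPointError):
            fit(ds, hp, seed=0)


class TestScore:
    def test_logistic_of_smoothed_product(self, rng):
        from nrlmfb.nrlmf_core import LatentModel

        U = rng.standard_normal((4, 2))
        V = rng.standard_normal((3, 2))
        model = LatentModel(U=U, V=V, U_smoothed=U, V_smoothed=V,
                            hyperparams=Hyperparameters(r=2))
        s = score(model)
        np.testing.assert_allclose(s, 1.0 / (1.0 + np.exp(-(U @ V.T))), rtol=1e-12)
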