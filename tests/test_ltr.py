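"""Latent tensor reconstruction: forward contract, tensor oracles, training."""

import itertools

import numpy as np
import pytest

from goltr.ltr import (LatentTensorReconstruction, LTRParams,
                       explicit_weight_tensor, fit_params, forward,
                       init_params, objective, polynomial_coefficient,
                       predict_scores, project_constraints)


def contract_oracle(T, xs):
    """Nested-loop contraction <T, x1 (x) x2 (x) ...> — independent of the model."""
    total = 0.0
    for idx in itertools.product(*(range(n) for n in T.shape)):
        term = T[idx]
        for d, j in enumerate(idx):
            term *= xs[d][j]
        total += term
    return total


def hand_model(activation="identity"):
    """n_d=1, n_t=1, 2 input features: output = x[0] under identity."""
    return LTRParams(
        U=[np.array([[1.0], [0.0]])], scale=[np.ones(2)],
        V=[np.array([[1.0]])], lam=np.array([1.0]),
        Q=np.array([[1.0]]), activation_A=activation,
        activation_B=activation,
    )


class TestForward:
    def test_hand_evaluation_identity(self):
        assert forward(hand_model(), (np.array([3.0, 5.0]),)) == \
            pytest.approx([3.0])

    def test_relu_gates_negative_projection(self):
        out = forward(hand_model("relu"), (np.array([-3.0, 5.0]),))
        assert out == pytest.approx([0.0])

    def test_shape_mismatch_names_view(self):
        with pytest.raises(ValueError, match="view 0"):
            forward(hand_model(), (np.array([1.0, 2.0, 3.0]),))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_tensor_contraction_oracle(self, seed):
        params = init_params([3, 4], 2, 2, seed=seed)
        params.Q = np.ones_like(params.Q)  # pre-projection output
        T = explicit_weight_tensor(params)
        rng = np.random.default_rng(seed + 50)
        xs = [rng.normal(size=3), rng.normal(size=4)]
        assert forward(params, xs)[0] == pytest.approx(
            contract_oracle(T, xs), abs=1e-8)

    def test_positive_homogeneity_under_relu(self):
        params = init_params([4, 3], 2, 3, activation_A="relu",
                             activation_B="relu", seed=2)
        rng = np.random.default_rng(0)
        xs = [rng.normal(size=4), rng.normal(size=3)]
        base = forward(params, xs)
        scaled = forward(params, [5.0 * xs[0], xs[1]])
        assert np.allclose(scaled, 5.0 * base)


class TestPredict:
    def test_single_sample_reduces_to_forward(self):
        params = init_params([3], 2, 2, seed=0)
        x = np.arange(3.0)
        assert np.allclose(predict_scores(params, [x[None, :]])[0],
                           forward(params, (x,)))

    def test_batch_equals_loop(self):
        params = init_params([3, 4], 5, 3, seed=1)
        rng = np.random.default_rng(2)
        X = [rng.normal(size=(20, 3)), rng.normal(size=(20, 4))]
        batch = predict_scores(params, X)
        for i in range(20):
            row = forward(params, (X[0][i], X[1][i]))
            assert np.allclose(batch[i], row, atol=1e-10)

    def test_permutation_equivariance(self):
        params = init_params([3, 4], 2, 2, seed=3)
        rng = np.random.default_rng(3)
        X = [rng.normal(size=(10, 3)), rng.normal(size=(10, 4))]
        perm = rng.permutation(10)
        assert np.allclose(predict_scores(params, [x[perm] for x in X]),
                           predict_scores(params, X)[perm])


class TestObjective:
    def test_perfect_fit_zero(self):
        params = init_params([3], 2, 2, seed=0)
        rng = np.random.default_rng(1)
        X = [rng.normal(size=(6, 3))]
        Y = predict_scores(params, X)
        assert objective(params, X, Y, 0.0) == 0.0

    def test_unit_error_half(self):
        params = hand_model()
        X = [np.array([[1.0, 0.0]])]
        Y = np.array([[0.0]])  # prediction is 1.0 everywhere off by 1
        assert objective(params, X, Y, 0.0) == pytest.approx(0.5)

    def test_matches_formula_oracle(self):
        params = init_params([3, 4], 4, 3, seed=5)
        rng = np.random.default_rng(5)
        X = [rng.normal(size=(8, 3)), rng.normal(size=(8, 4))]
        Y = rng.random((8, 4))
        C = 0.3
        Yhat = predict_scores(params, X)
        expected = (np.sum((Y - Yhat) ** 2) / (2 * 8 * 4)
                    + C / (2 * 3) * np.sum(params.lam ** 2))
        assert objective(params, X, Y, C) == pytest.approx(expected)

    def test_invariant_to_sample_permutation(self):
        params = init_params([3], 2, 2, seed=6)
        rng = np.random.default_rng(6)
        X = [rng.normal(size=(9, 3))]
        Y = rng.random((9, 2))
        perm = rng.permutation(9)
        assert objective(params, X, Y, 0.1) == pytest.approx(
            objective(params, [X[0][perm]], Y[perm], 0.1))


class TestConstraints:
    def test_row_rescaled(self):
        params = hand_model()
        params.V = [np.array([[3.0, 4.0], [0.0, 1.0]])]
        params.U = [np.eye(2)]
        out = project_constraints(params)
        assert np.allclose(out.V[0][0], [0.6, 0.8])

    def test_idempotent_on_feasible(self):
        params = init_params([4, 5], 3, 2, seed=1)
        out = project_constraints(params)
        for d in range(2):
            assert np.allclose(out.V[d], params.V[d], atol=1e-12)
            assert np.allclose(out.U[d], params.U[d], atol=1e-12)
        assert np.allclose(out.Q, params.Q, atol=1e-12)

    def test_random_infeasible_fixed(self):
        rng = np.random.default_rng(7)
        params = init_params([4, 5], 3, 2, seed=7)
        params.V = [5 * rng.normal(size=v.shape) for v in params.V]
        params.U = [0.01 * rng.normal(size=u.shape) for u in params.U]
        params.Q = np.zeros_like(params.Q)  # degenerate: random replacement
        out = project_constraints(params, seed=7)
        assert out.constraint_residuals() < 1e-10


class TestInit:
    def test_same_seed_identical(self):
        a = init_params([3, 4], 2, 3, seed=9)
        b = init_params([3, 4], 2, 3, seed=9)
        assert np.array_equal(a.lam, b.lam)
        assert all(np.array_equal(x, y) for x, y in zip(a.U, b.U))

    def test_feasible_at_init(self):
        assert init_params([6, 7], 3, 4, seed=0).constraint_residuals() < 1e-6

    def test_different_seeds_differ(self):
        assert not np.array_equal(init_params([3], 2, 2, seed=0).lam,
                                  init_params([3], 2, 2, seed=1).lam)


class TestFit:
    def test_epochs_zero_returns_projected_init(self):
        params = init_params([3], 2, 2, seed=0)
        out, report = fit_params(params, [np.ones((4, 3))],
                                 np.zeros((4, 2)), epochs=0)
        assert np.array_equal(out.lam, params.lam)
        assert report.epochs_run == 0

    def test_noiseless_planted_recovery_small(self):
        rng = np.random.default_rng(12)
        truth = init_params([10, 10], 3, 2, seed=12)
        truth.lam = np.array([1.0, -0.8])
        X = [rng.normal(size=(800, 10)) for _ in range(2)]
        Y = predict_scores(truth, X)
        est = init_params([10, 10], 3, 2, seed=99)
        est, report = fit_params(est, X, Y, epochs=250, batch_size=100,
                                 learning_rate=0.01, seed=99)
        assert report.objective[-1] < 1e-3

    def test_lambda_shrinks_on_zero_targets(self):
        params = init_params([4], 2, 3, seed=4)
        norm0 = np.linalg.norm(params.lam)
        X = [np.random.default_rng(4).normal(size=(50, 4))]
        out, _ = fit_params(params.copy(), X, np.zeros((50, 2)),
                            C_lambda=1.0, epochs=30, batch_size=25,
                            learning_rate=0.01, seed=4)
        assert np.linalg.norm(out.lam) < norm0

    def test_constraints_hold_every_epoch(self):
        params = init_params([5, 6], 2, 2, seed=8)
        rng = np.random.default_rng(8)
        X = [rng.normal(size=(40, 5)), rng.normal(size=(40, 6))]
        Y = rng.random((40, 2))
        _, report = fit_params(params, X, Y, epochs=10, batch_size=16, seed=8)
        assert all(r < 1e-6 for r in report.constraint_residuals)

    def test_validation_selects_best_model(self):
        rng = np.random.default_rng(3)
        truth = init_params([6], 2, 2, seed=3)
        X = [rng.normal(size=(60, 6))]
        Y = predict_scores(truth, X)
        est = init_params([6], 2, 2, seed=77)
        _, report = fit_params(est, [X[0][:40]], Y[:40], epochs=20,
                               X_val=[X[0][40:]], Y_val=Y[40:],
                               batch_size=20, seed=77)
        # hold-out objective was tracked for every epoch
        assert len(report.val_objective) == 20


class TestExplicitTensor:
    def test_rank_one_basis_vectors(self):
        params = LTRParams(
            U=[np.eye(3), np.eye(3)], scale=[np.ones(3), np.ones(3)],
            V=[np.array([[1.0, 0.0, 0.0]]), np.array([[0.0, 1.0, 0.0]])],
            lam=np.array([1.0]), Q=np.array([[1.0]]),
        )
        T = explicit_weight_tensor(params)
        expected = np.zeros((3, 3))
        expected[0, 1] = 1.0
        assert np.allclose(T, expected)

    def test_zero_lambda_zero_tensor(self):
        params = init_params([3, 4], 2, 2, seed=0)
        params.lam = np.zeros(2)
        assert not explicit_weight_tensor(params).any()

    def test_size_guard(self):
        params = init_params([200, 200, 200], 1, 1, seed=0)
        with pytest.raises(ValueError, match="size guard"):
            explicit_weight_tensor(params)

    def test_relu_refused(self):
        params = init_params([3], 1, 1, activation_B="relu", seed=0)
        with pytest.raises(ValueError):
            explicit_weight_tensor(params)

    def test_planted_rank2_unfolding_rank(self):
        from goltr.synthetic import SimConfig, plant_model
        cfg = SimConfig(seed=5, view_dims=(6, 7), n_t=2)
        params = plant_model(cfg, n_y=3)
        T = explicit_weight_tensor(params)
        unfold = T.reshape(T.shape[0], -1)
        assert np.linalg.matrix_rank(unfold, tol=1e-8) <= 2


class TestPolynomialCoefficient:
    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_tensor_entries(self, seed):
        params = init_params([4, 3, 2], 2, 3, seed=seed)
        T = explicit_weight_tensor(params)
        rng = np.random.default_rng(seed)
        for _ in range(50):
            idx = tuple(int(rng.integers(n)) for n in T.shape)
            assert polynomial_coefficient(params, idx) == pytest.approx(
                T[idx], abs=1e-10)

    def test_linear_in_lambda(self):
        params = init_params([3, 3], 2, 2, seed=1)
        c1 = polynomial_coefficient(params, (1, 2))
        params.lam = 2 * params.lam
        assert polynomial_coefficient(params, (1, 2)) == pytest.approx(2 * c1)

    def test_index_out_of_range(self):
        params = init_params([3, 3], 2, 2, seed=1)
        with pytest.raises(IndexError):
            polynomial_coefficient(params, (3, 0))


class TestEstimator:
    def test_sklearn_params_round_trip(self):
        est = LatentTensorReconstruction(n_t=4, epochs=3)
        est2 = LatentTensorReconstruction(**est.get_params())
        assert est2.get_params() == est.get_params()

    def test_fit_predict_shapes_and_clip(self):
        rng = np.random.default_rng(0)
        X = [rng.normal(size=(30, 5)), rng.normal(size=(30, 4))]
        Y = rng.integers(0, 2, size=(30, 3)).astype(float)
        est = LatentTensorReconstruction(n_t=2, epochs=5, batch_size=10,
                                         random_state=0).fit(X, Y)
        S = est.predict(X)
        assert S.shape == (30, 3)
        assert S.min() >= 0.0 and S.max() <= 1.0

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        X = [rng.normal(size=(20, 4))]
        Y = rng.integers(0, 2, size=(20, 2)).astype(float)
        est = LatentTensorReconstruction(n_t=2, epochs=3, batch_size=10,
                                         random_state=1).fit(X, Y)
        path = tmp_path / "model.npz"
        est.save(path)
        back = LatentTensorReconstruction.load(path)
        assert np.allclose(back.predict(X), est.predict(X))
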