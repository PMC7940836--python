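"""ADMM solver correctness against independent reference solvers."""

import numpy as np
import pytest

import mmsgl as M
from mmsgl import admm
from mmsgl.admm import _fista

from .conftest import TIGHT, make_problem
from .oracles import (
    full_objective,
    lasso_oracle,
    prox_scalar_oracle,
    smoothed_objective_solve,
)


def _design(space, X1, X2, y):
    return M.standardize([X1, X2], y, space=space)


class TestObjective:
    def test_zero_coefficients_give_squared_norm(self, small_problem):
        space, X1, X2, y, _ = small_problem
        D = M.build_gradient_operator(space)
        w = M.PenaltyWeights(1.0, 2.0, 3.0)
        z = np.zeros(space.p)
        assert M.objective([X1, X2], y, [z, z], w, D) == pytest.approx(y @ y)

    def test_no_penalty_is_rss(self, small_problem, rng):
        space, X1, X2, y, _ = small_problem
        D = M.build_gradient_operator(space)
        b1, b2 = rng.standard_normal(space.p), rng.standard_normal(space.p)
        resid = y - X1 @ b1 - X2 @ b2
        got = M.objective([X1, X2], y, [b1, b2], M.PenaltyWeights(0, 0, 0), D)
        assert got == pytest.approx(resid @ resid)

    def test_matches_independent_summation(self, rng):
        n, p = 5, 8
        space = M.build_voxel_space((p, 1, 1), np.ones((p, 1, 1), bool))
        D = M.build_gradient_operator(space)
        X1, X2 = rng.standard_normal((n, p)), rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        b1, b2 = rng.standard_normal(p), rng.standard_normal(p)
        w = M.PenaltyWeights(0.3, 0.7, 1.1)
        got = M.objective([X1, X2], y, [b1, b2], w, D)
        ref = full_objective(np.concatenate([b1, b2]), [X1, X2], y, w, D)
        assert got == pytest.approx(ref, rel=1e-12)

    def test_dimension_mismatch_raises(self, small_problem):
        space, X1, X2, y, _ = small_problem
        D = M.build_gradient_operator(space)
        with pytest.raises(ValueError):
            M.objective([X1, X2], y, [np.zeros(3), np.zeros(space.p)],
                        M.PenaltyWeights(1, 1, 1), D)


class TestSolve:
    def test_lasso_null_solution(self, small_problem):
        space, X1, X2, y, _ = small_problem
        design = _design(space, X1, X2, y)
        X = np.hstack(design.X_list)
        yc = y - y.mean()
        lam1 = 2.0 * np.abs(X.T @ yc).max() * 1.01
        bundle = M.build_operator_bundle(space, 2)
        fit = M.solve(design.X_list, y, bundle, M.PenaltyWeights(lam1, 0, 0), TIGHT)
        assert np.abs(fit.beta).max() == 0.0
        assert fit.support1.size == 0 and fit.support2.size == 0

    def test_matches_coordinate_descent_lasso(self, small_problem):
        space, X1, X2, y, _ = small_problem
        design = _design(space, X1, X2, y)
        bundle = M.build_operator_bundle(space, 2)
        lam1 = 0.8
        fit = M.solve(design.X_list, design.y, bundle,
                      M.PenaltyWeights(lam1, 0, 0), TIGHT)
        ref = lasso_oracle(np.hstack(design.X_list), design.y - design.y.mean(), lam1)
        np.testing.assert_allclose(fit.beta, ref, atol=1e-4)

    def test_full_penalty_matches_convex_oracle(self, small_problem):
        space, X1, X2, y, _ = small_problem
        design = _design(space, X1, X2, y)
        bundle = M.build_operator_bundle(space, 2)
        w = M.PenaltyWeights(0.4, 0.6, 0.9)
        fit = M.solve(design.X_list, design.y, bundle, w, TIGHT)
        yc = design.y - design.y.mean()
        _, obj_ref = smoothed_objective_solve(design.X_list, yc, w, bundle.D)
        obj = full_objective(fit.beta, design.X_list, yc, w, bundle.D)
        assert abs(obj - obj_ref) <= 1e-5 * abs(obj_ref)

    def test_feasible_at_convergence(self, small_problem):
        space, X1, X2, y, _ = small_problem
        bundle = M.build_operator_bundle(space, 2)
        settings = M.SolverSettings(tol_scale=1e-6)
        fit = M.solve([X1, X2], y, bundle, M.PenaltyWeights(0.5, 0.5, 0.5), settings)
        assert fit.converged
        gap = bundle.A @ fit.state.beta - fit.state.alpha
        eps_pri = settings.tol_scale * np.sqrt(bundle.A.shape[0])
        assert np.linalg.norm(gap) <= eps_pri

    def test_merit_nonincreasing_at_tail(self, small_problem):
        space, X1, X2, y, _ = small_problem
        bundle = M.build_operator_bundle(space, 2)
        fit = M.solve([X1, X2], y, bundle, M.PenaltyWeights(0.5, 0.7, 0.3), TIGHT)
        tail = fit.objective_trace[-10:]
        slack = 1e-7 * max(1.0, abs(tail[0]))
        assert np.all(np.diff(tail) <= slack)

    def test_nonconvergence_flagged_not_raised(self, small_problem):
        space, X1, X2, y, _ = small_problem
        bundle = M.build_operator_bundle(space, 2)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            fit = M.solve([X1, X2], y, bundle, M.PenaltyWeights(0.5, 0.5, 0.5),
                          M.SolverSettings(max_iter=2, tol_scale=1e-12))
        assert not fit.converged

    def test_nonfinite_input_raises(self, small_problem):
        space, X1, X2, y, _ = small_problem
        bundle = M.build_operator_bundle(space, 2)
        y_bad = y.copy()
        y_bad[0] = np.nan
        with pytest.raises(FloatingPointError):
            M.solve([X1, X2], y_bad, bundle, M.PenaltyWeights(0.5, 0.5, 0.0))

    def test_warm_start_agrees_with_cold_start(self, small_problem):
        space, X1, X2, y, _ = small_problem
        bundle = M.build_operator_bundle(space, 2)
        w_hot = M.PenaltyWeights(1.0, 0.5, 0.5)
        w_cold = M.PenaltyWeights(0.5, 0.25, 0.25)
        first = M.solve([X1, X2], y, bundle, w_hot, TIGHT)
        warm = M.solve([X1, X2], y, bundle, w_cold, TIGHT, init=first.state)
        cold = M.solve([X1, X2], y, bundle, w_cold, TIGHT)
        np.testing.assert_allclose(warm.beta, cold.beta, atol=2e-4)


class TestAlphaUpdate:
    """The alpha-step is the exact prox of the weighted L1 norm."""

    def test_zero_weight_leaves_argument(self, line_space, rng):
        bundle = M.build_operator_bundle(line_space, 2)
        v = rng.standard_normal(bundle.A.shape[0])
        lam = bundle.lambda_weights(0.0, 0.0)
        np.testing.assert_array_equal(M.soft_threshold(v, lam), v)

    def test_scalar_example(self):
        # threshold Lambda_ii / rho = 2 applied to 5
        assert M.soft_threshold(5.0, 2.0) == 3.0

    def test_coordinatewise_prox_optimality(self, rng):
        rho = 1.7
        for _ in range(50):
            z = float(rng.uniform(-4, 4))
            wgt = float(rng.uniform(0, 3))
            got = M.soft_threshold(z, wgt / rho)
            assert got == pytest.approx(prox_scalar_oracle(z, wgt, rho), abs=1e-3)


class TestBetaUpdate:
    def test_quadratic_case_matches_normal_equations(self, grid_space, rng):
        # lambda3 = 0: the subproblem is a strictly convex quadratic
        p = grid_space.p
        n = 15
        bundle = M.build_operator_bundle(grid_space, 1)
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        rho = 1.3
        target = rng.standard_normal(bundle.A.shape[0])
        A = bundle.A
        L = 2.0 * admm.design_norm_sq(X) + rho * bundle.AtA_norm()
        beta, _, _ = _fista(X, y, A, rho, target, 0.0, np.zeros(p), L, 1, p,
                            1e-14, 20000, None)
        H = 2.0 * X.T @ X + rho * (A.T @ A).toarray()
        ref = np.linalg.solve(H, 2.0 * X.T @ y + rho * (A.T @ target))
        np.testing.assert_allclose(beta, ref, atol=1e-6)

    def test_zero_data_gives_zero(self, grid_space):
        p = grid_space.p
        bundle = M.build_operator_bundle(grid_space, 1)
        X = np.zeros((5, p))
        beta, _, pg_res = _fista(X, np.zeros(5), bundle.A, 1.0,
                                 np.zeros(bundle.A.shape[0]), 0.5, np.zeros(p),
                                 1.0, 1, p, 1e-12, 100, None)
        assert pg_res == 0.0 and np.abs(beta).max() == 0.0

    def test_large_group_weight_zeros_pairs_jointly(self, rng):
        # p=2 toy: both modality coefficients at a voxel vanish together
        space = M.build_voxel_space((2, 1, 1), np.ones((2, 1, 1), bool))
        bundle = M.build_operator_bundle(space, 2)
        X1, X2 = rng.standard_normal((30, 2)), rng.standard_normal((30, 2))
        y = X1[:, 0] * 2 + X2[:, 0] * 1.5 + 0.05 * rng.standard_normal(30)
        w = M.PenaltyWeights(0.0, 0.0, 20.0)
        fit = M.solve([X1, X2], y, bundle, w, TIGHT)
        b = np.stack(fit.betas)  # (2 modalities, 2 voxels)
        for j in range(2):
            pair = b[:, j]
            assert (np.abs(pair) > 1e-8).all() or (np.abs(pair) <= 1e-8).all()
        # oracle agreement on the objective
        yc = y - y.mean()
        _, obj_ref = smoothed_objective_solve([X1, X2], yc, w, bundle.D)
        obj = full_objective(fit.beta, [X1, X2], yc, w, bundle.D)
        assert abs(obj - obj_ref) <= 1e-4 * max(1.0, abs(obj_ref))


class TestGroupKKT:
    def test_zero_pairs_satisfy_stationarity_bound(self, rng):
        """With only the group penalty, a voxel pair is zero iff the
        residual-correlation vector is inside the lambda3 ball."""
        space = M.build_voxel_space((10, 1, 1), np.ones((10, 1, 1), bool))
        bundle = M.build_operator_bundle(space, 2)
        X1, X2, y, _ = make_problem(space, n=25, seed=9)
        lam3 = 12.0
        fit = M.solve([X1, X2], y, bundle, M.PenaltyWeights(0, 0, lam3), TIGHT)
        yc = y - y.mean()
        r = yc - X1 @ fit.betas[0] - X2 @ fit.betas[1]
        g = 2.0 * np.stack([X1.T @ r, X2.T @ r])  # (2, p) block gradient
        norms = np.linalg.norm(g, axis=0)
        zero = np.abs(np.stack(fit.betas)).max(axis=0) <= 1e-8
        assert np.all(norms[zero] <= lam3 * (1 + 1e-2))
        assert np.all(np.abs(norms[~zero] - lam3) <= lam3 * 1e-2)
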