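"""Semi-blind deconvolution tests: exchange identity, kernel step, alternating loop."""

import numpy as np
import pytest
from scipy.optimize import LinearConstraint, minimize

from respyro import (
    BlindProblemSpec,
    TimeGrid,
    alternating_optimization,
    build_operator,
    build_signal_column_operator,
    initialize_h,
    make_test_problem,
    solve_h_step,
)
from respyro.blind import joint_objective, project_simplex
from respyro.synthetic import default_kernel


class TestSignalColumnOperator:
    def test_unit_signal_gives_identity_block(self):
        x = np.zeros(10)
        x[0] = 1.0
        A = build_signal_column_operator(x, support_s=4)
        dense = A.to_dense()
        np.testing.assert_array_equal(dense[:4], np.eye(4))
        np.testing.assert_array_equal(dense[4:], np.zeros((6, 4)))

    def test_exchange_identity(self, rng):
        """H~(h~) x~ == Hhat_s(x~) h~ for random feasible pairs."""
        for _ in range(10):
            m, s = 50, 9
            x = rng.standard_normal(m)
            h = np.abs(rng.standard_normal(s))
            h /= h.sum()
            col = np.zeros(m)
            col[:s] = h
            lhs = build_operator(col).matvec(x)
            rhs = build_signal_column_operator(x, s).matvec(h)
            np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_dense_oracle_40_by_7(self, rng):
        from scipy.linalg import toeplitz

        x = rng.standard_normal(40)
        A = build_signal_column_operator(x, 7)
        oracle = toeplitz(x, np.zeros(40))[:, :7]
        np.testing.assert_allclose(A.to_dense(), oracle, atol=1e-14)
        h = rng.standard_normal(7)
        np.testing.assert_allclose(A.matvec(h), oracle @ h, atol=1e-12)
        y = rng.standard_normal(40)
        np.testing.assert_allclose(A.rmatvec(y), oracle.T @ y, atol=1e-12)

    def test_out_of_range_support(self, rng):
        with pytest.raises(ValueError):
            build_signal_column_operator(rng.standard_normal(5), 6)


class TestSimplexProjection:
    def test_feasible_point_is_fixed(self):
        v = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(project_simplex(v), v, atol=1e-14)

    def test_matches_qp_oracle(self, rng):
        for _ in range(10):
            v = rng.standard_normal(8)
            p = project_simplex(v)
            res = minimize(lambda z: 0.5 * np.sum((z - v) ** 2), np.full(8, 1 / 8),
                           jac=lambda z: z - v,
                           constraints=[LinearConstraint(np.ones(8), 1.0, 1.0)],
                           bounds=[(0, None)] * 8, method="SLSQP",
                           options={"ftol": 1e-14, "maxiter": 500})
            np.testing.assert_allclose(p, res.x, atol=1e-6)
            assert p.min() >= 0 and abs(p.sum() - 1) < 1e-12


class TestHStep:
    def test_singleton_support_forced(self, rng):
        h = solve_h_step(rng.standard_normal(20), rng.standard_normal(20),
                         lambda_h=0.1, support_s=1)
        np.testing.assert_array_equal(h, [1.0])

    def test_noiseless_recovery_with_vanishing_regularization(self, rng):
        m, s = 60, 6
        h_star = np.abs(rng.standard_normal(s)) + 0.2
        h_star /= h_star.sum()
        x = rng.standard_normal(m)  # well-conditioned generic signal
        b = build_signal_column_operator(x, s).matvec(h_star)
        h = solve_h_step(x, b, lambda_h=1e-12, support_s=s)
        assert np.linalg.norm(h - h_star) < 1e-4

    def test_matches_generic_qp_solver(self, rng):
        m, s = 40, 5
        x = rng.standard_normal(m)
        b = rng.standard_normal(m)
        lam_h = 0.05
        h = solve_h_step(x, b, lam_h, s)
        A = build_signal_column_operator(x, s).to_dense()

        def fun(z):
            r = A @ z - b
            return r @ r + lam_h * z @ z

        res = minimize(fun, np.full(s, 1 / s),
                       jac=lambda z: 2 * (A.T @ (A @ z - b)) + 2 * lam_h * z,
                       constraints=[LinearConstraint(np.ones(s), 1.0, 1.0)],
                       bounds=[(0, None)] * s, method="SLSQP",
                       options={"ftol": 1e-16, "maxiter": 1000})
        assert fun(h) <= fun(res.x) + 1e-9
        np.testing.assert_allclose(h, res.x, atol=1e-5)

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            solve_h_step(np.zeros(10), np.ones(10), 0.1, 3)


class TestInitializeH:
    def test_uniform(self):
        np.testing.assert_allclose(initialize_h("uniform", 10), np.full(10, 0.1))

    @pytest.mark.parametrize("params", [{"alpha": 4.0, "beta": 3.0},
                                        {"alpha": 2.0, "beta": 0.5}])
    def test_gamma_presets_are_feasible(self, params):
        h = initialize_h("gamma_pdf", 184, dt=0.1, gamma_params=params)
        assert h.min() >= 0
        assert abs(h.sum() - 1.0) < 1e-12

    def test_gamma_shape_peaks_at_mode(self):
        # Gamma(alpha, beta) density peaks at (alpha-1)/beta
        h = initialize_h("gamma_pdf", 200, dt=0.1,
                         gamma_params={"alpha": 4.0, "beta": 3.0})
        t_peak = (np.argmax(h) + 1) * 0.1
        assert t_peak == pytest.approx(3.0 / 3.0, abs=0.1)

    def test_invalid(self):
        with pytest.raises(ValueError):
            initialize_h("gamma_pdf", 10, gamma_params={"alpha": -1, "beta": 1})
        with pytest.raises(ValueError):
            initialize_h("spline", 10)


class TestAlternatingOptimization:
    def _small_problem(self, seed=31, n=160, level=0.005):
        return make_test_problem(n=n, level=level, seed=seed)

    def test_fixed_point_sanity_from_truth(self):
        """Noiseless data, h0 = h*: the kernel barely moves, misfit stays small."""
        prob = make_test_problem(n=160, level=0.0, seed=32)
        d, s = prob.h.delay_d, prob.h.support_s
        h_star = prob.h.nonzero_part
        spec = BlindProblemSpec(b=prob.b_clean, delay_d=d, support_s=s,
                                h0=h_star, max_outer=5, lambda_h=1e-8,
                                lambda1=1e-4)
        rep = alternating_optimization(spec)
        assert np.linalg.norm(rep.h_tilde - h_star) / np.linalg.norm(h_star) < 0.05
        assert rep.residual_norms[-1] < 0.05 * np.linalg.norm(prob.b_clean)

    def test_all_kernel_iterates_feasible(self):
        prob = self._small_problem()
        spec = BlindProblemSpec(b=prob.b, delay_d=prob.h.delay_d,
                                support_s=prob.h.support_s, max_outer=8)
        rep = alternating_optimization(spec)
        for h in rep.h_iterates:
            assert h.min() >= -1e-10
            assert abs(h.sum() - 1.0) < 1e-10

    def test_joint_objective_nonincreasing(self):
        prob = self._small_problem(seed=33)
        spec = BlindProblemSpec(b=prob.b, delay_d=prob.h.delay_d,
                                support_s=prob.h.support_s, max_outer=10)
        rep = alternating_optimization(spec)
        obj = rep.objective_history
        slack = 1e-6 * obj[0]
        assert all(b <= a + slack for a, b in zip(obj, obj[1:]))

    def test_l2_x_step_variant_runs(self):
        prob = self._small_problem(seed=34)
        spec = BlindProblemSpec(b=prob.b, delay_d=prob.h.delay_d,
                                support_s=prob.h.support_s, max_outer=3,
                                x_step="l2", lambda2=0.05)
        rep = alternating_optimization(spec)
        assert rep.iterations == 3
        assert all(np.isfinite(rep.x_tilde))

    def test_recovers_kernel_shape_small_problem(self):
        prob = self._small_problem(seed=35)
        d, s = prob.h.delay_d, prob.h.support_s
        spec = BlindProblemSpec(b=prob.b, delay_d=d, support_s=s, max_outer=30)
        rep = alternating_optimization(spec)
        h_true = prob.h.nonzero_part
        ncc = rep.h_tilde @ h_true / (np.linalg.norm(rep.h_tilde) * np.linalg.norm(h_true))
        assert ncc > 0.7

    def test_invalid_specs(self, rng):
        b = rng.standard_normal(50)
        with pytest.raises(ValueError):
            BlindProblemSpec(b=b, delay_d=30, support_s=30)
        with pytest.raises(ValueError):
            BlindProblemSpec(b=b, delay_d=2, support_s=5, lambda1=-1.0)
        bad_h0 = np.full(5, 0.3)  # sums to 1.5
        with pytest.raises(ValueError):
            BlindProblemSpec(b=b, delay_d=2, support_s=5, h0=bad_h0)


class TestNonUniqueness:
    def test_shifted_pairs_produce_nearly_identical_observations(self):
        """Distinct (x, h) pairs with < 1% forward-image difference.

        Shifting the kernel right and the signal left by the same lag leaves
        the convolution unchanged except at the boundaries — the degeneracy
        that makes unconstrained blind deconvolution ill-posed.
        """
        grid = TimeGrid(n=256, dt=1.0)
        h1 = default_kernel(grid)
        x1 = np.zeros(256)
        x1[60:90] = 1.0
        x1[120:140] = 0.5
        lag = 3
        h2 = np.roll(h1.values, lag)
        x2 = np.roll(x1, -lag)
        b1 = build_operator(h1.values).matvec(x1)
        b2 = build_operator(h2).matvec(x2)
        assert np.linalg.norm(b1 - b2) / np.linalg.norm(b1) < 0.01
        # ... while the pairs themselves differ appreciably
        assert np.linalg.norm(h1.values - h2) / np.linalg.norm(h1.values) > 0.05
        assert np.linalg.norm(x1 - x2) / np.linalg.norm(x1) > 0.05
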