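"""Trajectory optimizer: LQR oracle, backward pass, convergence diagnostics."""

import numpy as np
import pytest

from prepctrl.costs import ControlTask
from prepctrl.ilqr import (
    ILQROptions,
    ToyProblem,
    backward_pass,
    build_reach_problem,
    input_gradient,
    solve,
)
from prepctrl.networks import NetworkModel, generate_2d, generate_readout, set_baseline


class LQProblem:
    """Linear dynamics z' = A z + B u with quadratic stage costs.

    Inputs enter the first ``m`` state coordinates with gain ``g`` (the
    structure the solver exploits), i.e. B = g [I_m; 0].
    """

    def __init__(self, A, m, g, Qx, Ru, Qf, z0, K):
        self.A, self.m, self.g = A, m, g
        self.Qx, self.Ru, self.Qf = Qx, Ru, Qf
        self.n_z, self.n_u, self.K = A.shape[0], m, K
        self.z0 = z0
        self.input_gain = g
        self.cost = self

    def step(self, z, u, k):
        zn = self.A @ z
        zn[: self.m] += self.g * u
        return zn

    def rollout(self, U):
        Z = np.empty((self.K + 1, self.n_z))
        Z[0] = self.z0
        for k in range(self.K):
            Z[k + 1] = self.step(Z[k], U[k], k)
        return Z

    def linearize(self, Z, U):
        return np.broadcast_to(self.A, (self.K, self.n_z, self.n_z))

    def total_cost(self, Z, U):
        J = sum(z @ self.Qx @ z for z in Z[:-1]) + Z[-1] @ self.Qf @ Z[-1]
        return float(J + sum(u @ self.Ru @ u for u in U))

    def total(self, Z, U):
        return self.total_cost(Z, U)

    class _Q:
        pass

    def _quad(self, z, u, Qx, Ru):
        q = self._Q()
        q.lx = 2 * Qx @ z
        q.lxx = 2 * Qx
        q.lu = 2 * Ru @ u
        q.luu = 2 * Ru
        q.lux = np.zeros((self.n_u, self.n_z))
        return q

    def quadratize(self, z, u, k):
        return self._quad(z, u, self.Qx, self.Ru)

    def quadratize_terminal(self, z):
        q = self._quad(z, np.zeros(self.n_u), self.Qf, self.Ru)
        return q

    def B_full(self):
        B = np.zeros((self.n_z, self.n_u))
        B[: self.m] = self.g * np.eye(self.m)
        return B


def riccati_optimum(p: LQProblem):
    """Independent finite-horizon LQR recursion (textbook form)."""
    A, B = p.A, p.B_full()
    S = p.Qf.copy()
    Ks = []
    for _ in range(p.K):
        G = p.Ru + B.T @ S @ B
        K = np.linalg.solve(G, B.T @ S @ A)
        S = p.Qx + A.T @ S @ A - A.T @ S @ B @ K
        Ks.append(K)
    Ks = Ks[::-1]
    z = p.z0.copy()
    U = np.empty((p.K, p.n_u))
    for k in range(p.K):
        U[k] = -Ks[k] @ z
        z = p.step(z, U[k], k)
    return float(p.z0 @ S @ p.z0), U


def random_lq(seed, n=6, m=2, K=50):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, n))
    A *= 0.95 / np.max(np.abs(np.linalg.eigvals(A)))
    Qx = np.diag(rng.uniform(0.1, 1.0, n))
    Ru = np.diag(rng.uniform(0.1, 1.0, m))
    Qf = np.diag(rng.uniform(0.5, 2.0, n))
    z0 = rng.standard_normal(n)
    return LQProblem(A, m, 0.7, Qx, Ru, Qf, z0, K)


def toy_problem(w=2.0, angle=np.pi / 2, dt=2.0, delay=400.0, movement=1000.0):
    model = generate_2d("feedforward", w)
    model.C = np.array([[np.cos(angle), np.sin(angle)]])
    task = ControlTask(delay=delay, movement=movement, theta_star=20.0,
                       alpha_effort=1e-5)
    return ToyProblem(model, task, dt)


class TestAgainstRiccati:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dynamic_programming_optimum(self, seed):
        p = random_lq(seed)
        j_opt, u_opt = riccati_optimum(p)
        sol = solve(p, options=ILQROptions(tol=1e-12, max_iter=50))
        assert abs(sol.cost - j_opt) / j_opt < 1e-8
        assert np.max(np.abs(sol.U - u_opt)) < 1e-6


class TestSolve:
    def test_already_optimal_start_accepts_zero_iterations(self):
        # start at the target with a target-only cost: u = 0 is optimal
        p = toy_problem()
        p.cost.w_null[:] = 0.0
        p.cost.y_star = 0.0
        sol = solve(p)
        assert sol.converged and sol.n_accepted == 0
        assert np.allclose(sol.U, 0.0)

    def test_cost_monotone_over_accepted_iterations(self):
        p = toy_problem()
        sol = solve(p)
        costs = [e["cost"] for e in sol.trace]
        assert all(b < a for a, b in zip(costs, costs[1:])) or len(costs) <= 1
        assert sol.trace[0]["prev_cost"] > sol.cost

    def test_deterministic(self):
        p = toy_problem()
        s1, s2 = solve(p), solve(p)
        assert np.array_equal(s1.U, s2.U) and s1.cost == s2.cost

    def test_feedback_invariance_to_init_perturbation(self):
        p = toy_problem()
        base = solve(p)
        rng = np.random.default_rng(0)
        pert = solve(p, u_init=rng.normal(0.0, 1e-3, (p.K, p.n_u)))
        assert abs(pert.cost - base.cost) / base.cost < 1e-3

    def test_gradient_small_at_convergence(self):
        p = toy_problem()
        U0 = np.zeros((p.K, p.n_u))
        g0 = np.linalg.norm(input_gradient(p, p.rollout(U0), U0))
        sol = solve(p, options=ILQROptions(tol=1e-10))
        g1 = np.linalg.norm(input_gradient(p, sol.Z, sol.U))
        assert g1 < 1e-3 * g0

    def test_expected_improvement_tracks_actual(self):
        p = toy_problem()
        sol = solve(p)
        last = sol.trace[-1]
        assert 0.5 < last["actual"] / last["expected"] < 1.5

    def test_nonfinite_init_rejected(self):
        p = toy_problem()
        with pytest.raises(ValueError):
            solve(p, u_init=np.full((p.K, p.n_u), np.nan))


class TestBackwardPass:
    def test_one_step_scalar_gain_closed_form(self):
        A = np.array([[1.3]])
        g, R, V = 0.6, 0.4, 2.0
        p = LQProblem(A, 1, g, np.zeros((1, 1)), np.array([[R]]),
                      np.array([[V]]), np.array([1.0]), 1)
        U = np.zeros((1, 1))
        Z = p.rollout(U)
        k_ff, K_fb, dV1, dV2 = backward_pass(p, Z, U, p.linearize(Z, U), mu=0.0)
        expected = -(R + g * V * g) ** -1 * g * V * A[0, 0]
        assert K_fb[0][0, 0] == pytest.approx(expected, rel=1e-12)

    def test_zero_cost_gives_zero_gains(self):
        A = np.eye(2)
        p = LQProblem(A, 2, 0.5, np.zeros((2, 2)), 1e-9 * np.eye(2),
                      np.zeros((2, 2)), np.ones(2), 5)
        U = np.zeros((5, 2))
        Z = p.rollout(U)
        k_ff, K_fb, dV1, dV2 = backward_pass(p, Z, U, p.linearize(Z, U), mu=0.0)
        assert np.allclose(k_ff, 0.0) and np.allclose(K_fb, 0.0)
        assert dV1 == 0.0 and dV2 == 0.0

    def test_indefinite_hessian_signalled_for_retry(self):
        # negative terminal curvature makes Quu indefinite at mu = 0
        A = np.array([[1.0]])
        p = LQProblem(A, 1, 1.0, np.zeros((1, 1)), np.array([[1e-6]]),
                      np.array([[-5.0]]), np.array([1.0]), 1)
        U = np.zeros((1, 1))
        Z = p.rollout(U)
        assert backward_pass(p, Z, U, p.linearize(Z, U), mu=0.0) is None
        assert backward_pass(p, Z, U, p.linearize(Z, U), mu=100.0) is not None


class TestProblemBuilders:
    def test_augmented_dimensions(self):
        toy = toy_problem()
        assert toy.n_z == 4 and toy.n_u == 2
        model = NetworkModel(W=np.zeros((20, 20)), tau=150.0)
        model.C = generate_readout(20, 2, seed=0)
        model = set_baseline(model, seed=0)
        task = ControlTask(delay=100.0, movement=500.0, theta0=np.zeros(2),
                           theta_star=np.zeros(2))
        from prepctrl.arm import ArmParams

        p = build_reach_problem(model, ArmParams(), task, 10.0)
        assert p.n_z == 24 and p.n_u == 20
        with pytest.raises(ValueError):
            build_reach_problem(model, "pendulum", task, 10.0)

    def test_reach_jacobians_match_finite_differences(self):
        from prepctrl.arm import ArmParams
        from prepctrl.networks import generate_isn

        model = generate_isn(n=12, seed=3, exc_scale=0.5)
        model.C = generate_readout(12, 2, seed=3)
        model = set_baseline(model, seed=3)
        task = ControlTask(delay=100.0, movement=400.0, theta0=np.array([0.2, 0.3]),
                           theta_star=np.array([0.4, 0.1]))
        p = build_reach_problem(model, ArmParams(), task, 10.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            z = np.concatenate(
                [model.rest_rate + rng.uniform(0.5, 1.5, 12),  # away from kinks
                 rng.uniform(-0.5, 0.5, 2), rng.uniform(-2, 2, 2)]
            )
            u = rng.standard_normal(12)
            Z = np.tile(z, (p.K + 1, 1))
            F = p.linearize(Z, np.tile(u, (p.K, 1)))[0]
            eps = 1e-6
            for i in range(p.n_z):
                e = np.zeros(p.n_z)
                e[i] = eps
                num = (p.step(z + e, u, 0) - p.step(z - e, u, 0)) / (2 * eps)
                assert np.allclose(F[:, i], num, rtol=1e-5, atol=1e-7)
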