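"""Cost functionals: closed-form integrals, linearity, expansions."""

import numpy as np
import pytest

from prepctrl.costs import (
    ControlTask,
    CostBreakdown,
    SequenceCost,
    SingleReachCost,
    ToyReachCost,
    sequence_cost,
    single_reach_cost,
    toy_reach_cost,
)
from prepctrl.networks import NetworkModel, generate_2d, generate_readout, set_baseline


def arm_model(n=12, seed=0):
    model = NetworkModel(W=np.zeros((n, n)), tau=150.0, nonlinearity="relu")
    model.C = generate_readout(n, 2, seed=seed)
    return set_baseline(model, seed=seed)


def frozen_trajectory(model, task, dt, theta=None):
    """Network at rest, arm frozen at a posture, zero inputs."""
    K = task.n_steps(dt)
    theta = np.asarray(task.theta0 if theta is None else theta, float).reshape(2)
    Z = np.tile(np.concatenate([model.rest_rate, theta, np.zeros(2)]), (K + 1, 1))
    U = np.zeros((K, model.n))
    return Z, U


class TestSingleReach:
    def test_at_target_at_rest_all_terms_zero(self):
        model = arm_model()
        task = ControlTask(delay=100.0, movement=500.0, theta0=np.array([0.3, -0.5]),
                           theta_star=np.array([0.3, -0.5]))
        Z, U = frozen_trajectory(model, task, 10.0)
        b = single_reach_cost(Z, U, task, model, 10.0)
        assert b.total == 0.0

    def test_frozen_hand_cost_is_one_third_error_squared(self):
        # J = ||dtheta||^2 * int_0^T t^2/T^3 dt = ||dtheta||^2 / 3
        model = arm_model()
        theta0 = np.array([0.5, -1.0])
        theta_star = np.array([0.9, -0.4])
        task = ControlTask(delay=0.0, movement=900.0, theta0=theta0,
                           theta_star=theta_star)
        Z, U = frozen_trajectory(model, task, 1.0)
        b = single_reach_cost(Z, U, task, model, 1.0)
        expected = np.sum((theta0 - theta_star) ** 2) / 3.0
        assert b.target == pytest.approx(expected, rel=3e-3)
        assert b.null == 0.0 and b.effort == 0.0

    def test_constant_input_effort_closed_form(self):
        model = arm_model()
        task = ControlTask(delay=300.0, movement=900.0, theta0=np.zeros(2),
                           theta_star=np.zeros(2), alpha_effort=2.5e-4)
        Z, U = frozen_trajectory(model, task, 10.0)
        c = 0.7
        U[:] = c
        b = single_reach_cost(Z, U, task, model, 10.0)
        expected = 2.5e-4 * (model.n * c**2) * (900.0 + 300.0) / (model.n * 900.0)
        assert b.effort == pytest.approx(expected, rel=1e-12)

    def test_breakdown_total_is_sum_of_parts(self):
        b = CostBreakdown(target=0.2, null=0.1, effort=0.05, pause=0.01)
        assert b.total == pytest.approx(0.36, abs=1e-15)
        with pytest.raises(ValueError):
            CostBreakdown(target=-1.0, null=0.0, effort=0.0)

    def test_urgency_weights_late_errors_more(self):
        model = arm_model()
        task = ControlTask(delay=0.0, movement=600.0, theta0=np.zeros(2),
                           theta_star=np.zeros(2))
        dt = 10.0
        K = task.n_steps(dt)
        ramp = np.linspace(1.0, 0.0, K + 1)  # error decays early vs late
        Z_early = np.zeros((K + 1, model.n + 4))
        Z_late = np.zeros((K + 1, model.n + 4))
        Z_early[:, :model.n] = model.rest_rate
        Z_late[:, :model.n] = model.rest_rate
        Z_early[:, model.n] = ramp
        Z_late[:, model.n] = ramp[::-1]
        U = np.zeros((K, model.n))
        early = single_reach_cost(Z_early, U, task, model, dt).target
        late = single_reach_cost(Z_late, U, task, model, dt).target
        assert late > early

    def test_costs_stable_under_dt_refinement(self):
        model = arm_model()
        theta = np.array([0.2, 0.4])
        task = ControlTask(delay=200.0, movement=800.0, theta0=np.zeros(2),
                           theta_star=np.array([1.0, -1.0]))
        totals = []
        for dt in (10.0, 5.0):
            Z, U = frozen_trajectory(model, task, dt, theta=theta)
            U[:] = 0.3
            totals.append(single_reach_cost(Z, U, task, model, dt).total)
        assert abs(totals[0] - totals[1]) / totals[1] < 0.02

    def test_window_mismatch_rejected(self):
        model = arm_model()
        task = ControlTask(delay=100.0, movement=500.0, theta0=np.zeros(2),
                           theta_star=np.zeros(2))
        Z, U = frozen_trajectory(model, task, 10.0)
        with pytest.raises(ValueError):
            single_reach_cost(Z[:-3], U, task, model, 10.0)


class TestToyReach:
    def toy_model(self):
        m = generate_2d("feedforward", 2.0)
        m.C = np.array([[1.0, 0.0]])
        return m

    def test_degenerate_target_zero(self):
        model = self.toy_model()
        task = ControlTask(delay=100.0, movement=400.0, theta_star=0.0)
        K = task.n_steps(2.0)
        b = toy_reach_cost(np.zeros((K + 1, 4)), np.zeros((K, 2)), task, model, 2.0)
        assert b.total == 0.0

    def test_frozen_output_cost_400_over_3(self):
        model = self.toy_model()
        task = ControlTask(delay=0.0, movement=1000.0, theta_star=20.0)
        K = task.n_steps(1.0)
        b = toy_reach_cost(np.zeros((K + 1, 4)), np.zeros((K, 2)), task, model, 1.0)
        assert b.target == pytest.approx(400.0 / 3.0, rel=3e-3)

    def test_effort_linear_in_weight(self):
        model = self.toy_model()
        rng = np.random.default_rng(0)
        task1 = ControlTask(delay=100.0, movement=400.0, theta_star=20.0,
                            alpha_effort=1e-5)
        task2 = ControlTask(delay=100.0, movement=400.0, theta_star=20.0,
                            alpha_effort=2e-5)
        K = task1.n_steps(2.0)
        Z = rng.standard_normal((K + 1, 4))
        U = rng.standard_normal((K, 2))
        b1 = toy_reach_cost(Z, U, task1, model, 2.0)
        b2 = toy_reach_cost(Z, U, task2, model, 2.0)
        assert b2.effort == pytest.approx(2 * b1.effort, rel=1e-12)
        assert b2.target == b1.target and b2.null == b1.null


class TestSequence:
    def test_pause_term_zero_when_hand_still(self):
        model = arm_model()
        task = ControlTask(delay=100.0, movement=1500.0, theta0=np.zeros(2),
                           theta_star=np.array([0.1, 0.2]),
                           theta_star2=np.array([0.3, -0.2]),
                           move1=300.0, pause=600.0)
        Z, U = frozen_trajectory(model, task, 10.0, theta=np.array([0.1, 0.2]))
        b = sequence_cost(Z, U, task, model, 10.0)
        assert b.pause == 0.0

    def test_second_urgency_weight_restarts_at_switch(self):
        model = arm_model()
        task = ControlTask(delay=0.0, movement=1500.0, theta0=np.zeros(2),
                           theta_star=np.zeros(2), theta_star2=np.ones(2),
                           move1=300.0, pause=600.0)
        cost = SequenceCost(task, model, 10.0)
        t = task.times(10.0)
        k_switch = int(np.argmin(np.abs(t - 900.0)))
        assert cost.w_tgt2[k_switch] == 0.0
        assert cost.w_tgt2[k_switch + 1] > 0.0
        assert np.all(cost.w_tgt[t > 900.0 + 1e-9] == 0.0)

    def test_degenerate_sequence_equals_single_reach(self):
        # zero first-reach window, zero pause, equal targets: the second
        # urgency clock coincides with the single-reach clock
        model = arm_model()
        star = np.array([0.4, -0.2])
        kw = dict(delay=200.0, movement=900.0, theta0=np.zeros(2), theta_star=star)
        seq_task = ControlTask(**kw, theta_star2=star, move1=0.0, pause=0.0,
                               alpha_pause=0.0)
        single_task = ControlTask(**kw)
        rng = np.random.default_rng(3)
        K = seq_task.n_steps(10.0)
        Z = rng.standard_normal((K + 1, model.n + 4))
        U = rng.standard_normal((K, model.n))
        b_seq = sequence_cost(Z, U, seq_task, model, 10.0)
        b_single = single_reach_cost(Z, U, single_task, model, 10.0)
        assert b_seq.total == pytest.approx(b_single.total, rel=1e-12)


class TestQuadratize:
    @pytest.mark.parametrize("which", ["single", "toy", "sequence"])
    def test_expansion_matches_finite_differences(self, which):
        rng = np.random.default_rng(12)
        if which == "toy":
            model = generate_2d("oscillatory", 1.5)
            model.C = np.array([[0.6, 0.8]])
            task = ControlTask(delay=100.0, movement=400.0, theta_star=20.0)
            cost = ToyReachCost(task, model, 2.0)
        else:
            model = arm_model(n=8, seed=2)
            kw = dict(delay=200.0, movement=800.0, theta0=np.array([0.2, 0.3]),
                      theta_star=np.array([0.5, -0.1]))
            if which == "sequence":
                task = ControlTask(**kw, theta_star2=np.array([0.1, 0.1]),
                                   move1=200.0, pause=100.0)
                cost = SequenceCost(task, model, 10.0)
            else:
                task = ControlTask(**kw)
                cost = SingleReachCost(task, model, 10.0)

        def stage(z, u, k):
            Z = np.zeros((cost.K + 1, cost.n_z))
            U = np.zeros((cost.K, cost.n_u))
            Z[k] = z
            if k < cost.K:
                U[k] = u
            return cost.breakdown(Z, U).total

        eps = 1e-5
        for k in [0, cost.K // 3, 2 * cost.K // 3, cost.K - 1]:
            # keep x away from rectification kinks
            z = rng.standard_normal(cost.n_z) + 2.0
            u = rng.standard_normal(cost.n_u)
            q = cost.quadratize(z, u, k)
            for i in range(cost.n_z):
                e = np.zeros(cost.n_z)
                e[i] = eps
                num = (stage(z + e, u, k) - stage(z - e, u, k)) / (2 * eps)
                assert q.lx[i] == pytest.approx(num, rel=1e-4, abs=1e-7)
            for i in range(cost.n_u):
                e = np.zeros(cost.n_u)
                e[i] = eps
                num = (stage(z, u + e, k) - stage(z, u - e, k)) / (2 * eps)
                assert q.lu[i] == pytest.approx(num, rel=1e-4, abs=1e-9)

    def test_effort_hessian_exact(self):
        model = arm_model(n=8, seed=2)
        task = ControlTask(delay=0.0, movement=500.0, theta0=np.zeros(2),
                           theta_star=np.zeros(2), alpha_effort=3e-4)
        cost = SingleReachCost(task, model, 10.0)
        q = cost.quadratize(np.zeros(cost.n_z), np.zeros(cost.n_u), 3)
        expected = 2 * 3e-4 * 10.0 / (8 * 500.0)
        assert np.allclose(q.luu, expected * np.eye(8))

    def test_target_gradient_zero_at_target(self):
        model = arm_model(n=8, seed=2)
        star = np.array([0.2, 0.4])
        task = ControlTask(delay=0.0, movement=500.0, theta0=star, theta_star=star)
        cost = SingleReachCost(task, model, 10.0)
        z = np.concatenate([model.rest_rate, star, np.zeros(2)])
        q = cost.quadratize(z, np.zeros(8), cost.K // 2)
        assert np.allclose(q.lx, 0.0)
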