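"""Task cost functionals and their local quadratic expansions.

Three objectives are implemented, all sharing the same structure: a
target-tracking term with a quadratic-in-time "urgency" weight over the
movement epoch, a stillness penalty over the delay epoch, and a control
effort penalty over the whole trial.

For the arm task, with joint angles theta, target theta*, start theta0 and
torques m = C phi(x):

    J = sum_{t in [0,T]} ||theta - theta*||^2 (t^2/T^2) dt/T
      + a_null sum_{t in [-Dprep,0)} (||theta - theta0||^2 + ||omega||^2
                                      + ||m||^2) dt/T
      + a_effort sum_{t in [-Dprep,T]} ||u||^2 dt/(N T).

The 1D toy task replaces (theta, omega, m) by the output position y, its
velocity and its acceleration y_dd = C x, with effort normalizer 2 (the
unit count).  The two-reach sequence objective adds a pause penalty
a_pause ||omega||^2 on an enforced hold window at the first target and a
second urgency term whose clock restarts when the hold ends; the sequence
terms use the same dt/T normalization as the single reach so that weights
remain comparable across tasks.

Time is discretized on a uniform grid t_k = -Dprep + k dt, k = 0..K.  Stage
costs use (z_k, u_k) for k < K plus a terminal target term at t_K = T; the
go-cue sample t = 0 belongs to the movement epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ControlTask",
    "CostBreakdown",
    "SingleReachCost",
    "ToyReachCost",
    "SequenceCost",
    "single_reach_cost",
    "toy_reach_cost",
    "sequence_cost",
]


@dataclass(frozen=True)
class ControlTask:
    """Delay/movement horizons, targets and cost weights for one problem.

    Times are in ms.  ``theta_star`` is the reach target in joint space for
    arm tasks, or the scalar target position for the 1D toy task.  Sequence
    fields (``theta_star2``, ``move1``, ``pause``, ``alpha_pause``) are only
    used by :class:`SequenceCost`.
    """

    delay: float
    movement: float
    theta0: np.ndarray | float = 0.0
    theta_star: np.ndarray | float = 0.0
    alpha_null: float = 1.0
    alpha_effort: float = 5e-7
    theta_star2: np.ndarray | None = None
    move1: float = 300.0
    pause: float = 600.0
    alpha_pause: float = 100.0

    def __post_init__(self) -> None:
        if self.delay < 0 or self.movement <= 0:
            raise ValueError("delay must be >= 0 and movement > 0")
        if min(self.alpha_null, self.alpha_effort, self.alpha_pause) < 0:
            raise ValueError("cost weights must be nonnegative")

    def n_steps(self, dt: float) -> int:
        K = int(round((self.delay + self.movement) / dt))
        if abs(K * dt - (self.delay + self.movement)) > 1e-9:
            raise ValueError("delay + movement must be a multiple of dt")
        return K

    def times(self, dt: float) -> np.ndarray:
        """Grid t_k = -delay + k dt, k = 0..K (K+1 samples)."""
        return -self.delay + dt * np.arange(self.n_steps(dt) + 1)


@dataclass(frozen=True)
class CostBreakdown:
    """Per-term decomposition of a trajectory's cost."""

    target: float
    null: float
    effort: float
    pause: float = 0.0

    def __post_init__(self) -> None:
        for name in ("target", "null", "effort", "pause"):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"cost term {name} must be nonnegative")

    @property
    def total(self) -> float:
        return self.target + self.null + self.effort + self.pause


class _QuadTerms:
    """Container for one stage's gradients/Hessians in (z, u)."""

    __slots__ = ("lx", "lu", "lxx", "luu", "lux")

    def __init__(self, n, m):
        self.lx = np.zeros(n)
        self.lu = np.zeros(m)
        self.lxx = np.zeros((n, n))
        self.luu = np.zeros((m, m))
        self.lux = np.zeros((m, n))


class SingleReachCost:
    """Delayed single-reach objective for the network+arm plant.

    The augmented state is z = [x (N neural activations); theta (2);
    omega (2)].  Torques m = C phi(x) enter the stillness penalty, which
    makes the stage cost piecewise-quadratic in x; its expansion uses the
    Gauss-Newton approximation with the rectified-linear subgradient taken
    as 0 at the kink.
    """

    def __init__(self, task: ControlTask, model, dt: float):
        self.task = task
        self.model = model
        self.dt = dt
        self.K = task.n_steps(dt)
        self.t = task.times(dt)
        self.n_x = model.n
        self.n_u = model.n
        self.n_z = model.n + 4
        T = task.movement
        # per-step weights; movement mask includes the go-cue sample
        self.w_tgt = np.where(self.t >= -1e-9, (self.t / T) ** 2 * dt / T, 0.0)
        self.w_null = np.where(self.t < -1e-9, task.alpha_null * dt / T, 0.0)
        self.w_eff = task.alpha_effort * dt / (self.n_u * T)
        self.theta0 = np.asarray(task.theta0, dtype=float).reshape(2)
        self.theta_star = np.asarray(task.theta_star, dtype=float).reshape(2)

    # --- evaluation ---------------------------------------------------

    def _tgt_err(self, theta: np.ndarray, k: int) -> np.ndarray:
        return theta - self.theta_star

    def breakdown(self, Z: np.ndarray, U: np.ndarray) -> CostBreakdown:
        """Cost terms for a state trajectory Z (K+1, n_z) and inputs U (K, n_u)."""
        if Z.shape[0] != self.K + 1 or U.shape[0] != self.K:
            raise ValueError("trajectory does not match the task window and dt")
        N = self.n_x
        theta = Z[:, N : N + 2]
        omega = Z[:, N + 2 : N + 4]
        m = self.model.torque(self.model.phi(Z[:, :N]))
        err = theta - self.theta_star[None, :]
        j_tgt = float(np.sum(self.w_tgt * np.sum(err**2, axis=1)))
        still = (
            np.sum((theta - self.theta0[None, :]) ** 2, axis=1)
            + np.sum(omega**2, axis=1)
            + np.sum(m**2, axis=1)
        )
        j_null = float(np.sum(self.w_null * still))
        j_eff = float(self.w_eff * np.sum(U**2))
        return CostBreakdown(target=j_tgt, null=j_null, effort=j_eff)

    def total(self, Z: np.ndarray, U: np.ndarray) -> float:
        return self.breakdown(Z, U).total

    # --- quadratic expansion for the trajectory optimizer -------------

    def quadratize(self, z: np.ndarray, u: np.ndarray, k: int) -> _QuadTerms:
        q = _QuadTerms(self.n_z, self.n_u)
        N = self.n_x
        theta = z[N : N + 2]
        if self.w_tgt[k] > 0.0:
            e = self._tgt_err(theta, k)
            q.lx[N : N + 2] += 2.0 * self.w_tgt[k] * e
            q.lxx[N : N + 2, N : N + 2] += 2.0 * self.w_tgt[k] * np.eye(2)
        if self.w_null[k] > 0.0:
            w = self.w_null[k]
            omega = z[N + 2 : N + 4]
            q.lx[N : N + 2] += 2.0 * w * (theta - self.theta0)
            q.lxx[N : N + 2, N : N + 2] += 2.0 * w * np.eye(2)
            q.lx[N + 2 : N + 4] += 2.0 * w * omega
            q.lxx[N + 2 : N + 4, N + 2 : N + 4] += 2.0 * w * np.eye(2)
            d = self.model.phi_prime(z[:N])
            m = self.model.torque(self.model.phi(z[:N]))
            CD = self.model.C * d[None, :]
            q.lx[:N] += 2.0 * w * (CD.T @ m)
            q.lxx[:N, :N] += 2.0 * w * (CD.T @ CD)
        if k < self.K:
            q.lu[:] = 2.0 * self.w_eff * u
            q.luu[:] = 2.0 * self.w_eff * np.eye(self.n_u)
        return q

    def quadratize_terminal(self, z: np.ndarray) -> _QuadTerms:
        q = self.quadratize(z, np.zeros(self.n_u), self.K)
        return q


class SequenceCost(SingleReachCost):
    """Two-reach sequence objective (double/compound reaches).

    The first urgency term tracks ``theta_star`` on [0, move1 + pause]; a
    pause penalty ``alpha_pause ||omega||^2`` applies on
    [move1, move1 + pause]; a second urgency term tracks ``theta_star2`` on
    the remainder with clock (t - move1 - pause)^2 / T^2.
    """

    def __init__(self, task: ControlTask, model, dt: float):
        if task.theta_star2 is None:
            raise ValueError("sequence task requires theta_star2")
        if not task.move1 + task.pause < task.movement:
            raise ValueError("move1 + pause must be smaller than the movement window")
        super().__init__(task, model, dt)
        T = task.movement
        t = self.t
        t_switch = task.move1 + task.pause
        self.theta_star2 = np.asarray(task.theta_star2, dtype=float).reshape(2)
        in_first = (t >= -1e-9) & (t <= t_switch + 1e-9)
        in_second = t > t_switch + 1e-9
        self.w_tgt = np.where(in_first, (t / T) ** 2 * dt / T, 0.0)
        self.w_tgt2 = np.where(
            in_second, ((t - t_switch) / T) ** 2 * dt / T, 0.0
        )
        in_pause = (t >= task.move1 - 1e-9) & (t <= t_switch + 1e-9)
        self.w_pause = np.where(in_pause, task.alpha_pause * dt / T, 0.0)

    def breakdown(self, Z: np.ndarray, U: np.ndarray) -> CostBreakdown:
        base = super().breakdown(Z, U)
        N = self.n_x
        theta = Z[:, N : N + 2]
        omega = Z[:, N + 2 : N + 4]
        err2 = theta - self.theta_star2[None, :]
        j_tgt2 = float(np.sum(self.w_tgt2 * np.sum(err2**2, axis=1)))
        j_pause = float(np.sum(self.w_pause * np.sum(omega**2, axis=1)))
        return CostBreakdown(
            target=base.target + j_tgt2,
            null=base.null,
            effort=base.effort,
            pause=j_pause,
        )

    def quadratize(self, z: np.ndarray, u: np.ndarray, k: int) -> _QuadTerms:
        q = super().quadratize(z, u, k)
        N = self.n_x
        if self.w_tgt2[k] > 0.0:
            e = z[N : N + 2] - self.theta_star2
            q.lx[N : N + 2] += 2.0 * self.w_tgt2[k] * e
            q.lxx[N : N + 2, N : N + 2] += 2.0 * self.w_tgt2[k] * np.eye(2)
        if self.w_pause[k] > 0.0:
            omega = z[N + 2 : N + 4]
            q.lx[N + 2 : N + 4] += 2.0 * self.w_pause[k] * omega
            q.lxx[N + 2 : N + 4, N + 2 : N + 4] += 2.0 * self.w_pause[k] * np.eye(2)
        return q


class ToyReachCost:
    """1D toy-task objective for a two-unit network driving output
    acceleration y_dd = C x.

    Augmented state z = [x (2); y; y_dot].  All terms are exactly quadratic
    (identity nonlinearity), so the expansion is exact.  The effort
    normalizer is the unit count (2).
    """

    def __init__(self, task: ControlTask, model, dt: float):
        self.task = task
        self.model = model
        self.dt = dt
        self.K = task.n_steps(dt)
        self.t = task.times(dt)
        self.n_x = model.n
        self.n_u = model.n
        self.n_z = model.n + 2
        T = task.movement
        self.w_tgt = np.where(self.t >= -1e-9, (self.t / T) ** 2 * dt / T, 0.0)
        self.w_null = np.where(self.t < -1e-9, task.alpha_null * dt / T, 0.0)
        self.w_eff = task.alpha_effort * dt / (self.n_u * T)
        self.y_star = float(np.asarray(task.theta_star).reshape(()))
        self.C = np.asarray(model.C, dtype=float).reshape(1, model.n)

    def breakdown(self, Z: np.ndarray, U: np.ndarray) -> CostBreakdown:
        if Z.shape[0] != self.K + 1 or U.shape[0] != self.K:
            raise ValueError("trajectory does not match the task window and dt")
        N = self.n_x
        y = Z[:, N]
        ydot = Z[:, N + 1]
        ydd = Z[:, :N] @ self.C[0]
        j_tgt = float(np.sum(self.w_tgt * (y - self.y_star) ** 2))
        j_null = float(np.sum(self.w_null * (y**2 + ydot**2 + ydd**2)))
        j_eff = float(self.w_eff * np.sum(U**2))
        return CostBreakdown(target=j_tgt, null=j_null, effort=j_eff)

    def total(self, Z: np.ndarray, U: np.ndarray) -> float:
        return self.breakdown(Z, U).total

    def quadratize(self, z: np.ndarray, u: np.ndarray, k: int) -> _QuadTerms:
        q = _QuadTerms(self.n_z, self.n_u)
        N = self.n_x
        if self.w_tgt[k] > 0.0:
            q.lx[N] += 2.0 * self.w_tgt[k] * (z[N] - self.y_star)
            q.lxx[N, N] += 2.0 * self.w_tgt[k]
        if self.w_null[k] > 0.0:
            w = self.w_null[k]
            q.lx[N] += 2.0 * w * z[N]
            q.lxx[N, N] += 2.0 * w
            q.lx[N + 1] += 2.0 * w * z[N + 1]
            q.lxx[N + 1, N + 1] += 2.0 * w
            ydd = float(self.C[0] @ z[:N])
            q.lx[:N] += 2.0 * w * ydd * self.C[0]
            q.lxx[:N, :N] += 2.0 * w * np.outer(self.C[0], self.C[0])
        if k < self.K:
            q.lu[:] = 2.0 * self.w_eff * u
            q.luu[:] = 2.0 * self.w_eff * np.eye(self.n_u)
        return q

    def quadratize_terminal(self, z: np.ndarray) -> _QuadTerms:
        return self.quadratize(z, np.zeros(self.n_u), self.K)


# ---------------------------------------------------------------------------
# Functional interfaces operating on plain trajectory arrays
# ---------------------------------------------------------------------------


def single_reach_cost(Z: np.ndarray, U: np.ndarray, task: ControlTask, model, dt: float) -> CostBreakdown:
    """Cost breakdown of an augmented-state trajectory for the arm task."""
    return SingleReachCost(task, model, dt).breakdown(Z, U)


def toy_reach_cost(Z: np.ndarray, U: np.ndarray, task: ControlTask, model, dt: float) -> CostBreakdown:
    """Cost breakdown for the 1D toy task."""
    return ToyReachCost(task, model, dt).breakdown(Z, U)


def sequence_cost(Z: np.ndarray, U: np.ndarray, task: ControlTask, model, dt: float) -> CostBreakdown:
    """Cost breakdown for a two-reach sequence."""
    return SequenceCost(task, model, dt).breakdown(Z, U)
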