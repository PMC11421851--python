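"""Iterative LQR trajectory optimization for the network+effector plant.

The solver follows the classic iterative linear-quadratic-regulator scheme:
linearize the discrete dynamics and quadratize the cost around the current
trajectory, solve the resulting time-varying LQ problem by a backward
dynamic-programming pass, and roll the affine control law forward with a
backtracking line search.  The control Hessian is regularized through the
value function (a Levenberg-Marquardt term on V_xx) with a multiplicative
up/down schedule, so non-positive-definite curvature triggers a retried
backward pass rather than a silent failure.

Dynamics are Euler-discretized at a uniform step ``dt`` (ms).  Control
inputs enter only the neural block of the augmented state, with constant
gain dt/tau; the backward pass exploits this structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arm import ArmParams, arm_acceleration, arm_jacobians
from .costs import ControlTask, SequenceCost, SingleReachCost, ToyReachCost
from .networks import NetworkModel

__all__ = [
    "ILQROptions",
    "OptimalSolution",
    "DivergenceError",
    "ReachProblem",
    "ToyProblem",
    "build_reach_problem",
    "backward_pass",
    "solve",
    "input_gradient",
]

_MS = 1e-3  # ms -> s, for the effector half of the state


class DivergenceError(RuntimeError):
    """Forward rollout produced non-finite states at every line-search step."""


@dataclass(frozen=True)
class ILQROptions:
    """Solver tolerances and budgets."""

    max_iter: int = 200
    tol: float = 1e-6  # relative cost-decrease tolerance
    reg_init: float = 1e-6
    reg_min: float = 1e-9
    reg_max: float = 1e9
    reg_up: float = 2.0
    reg_down: float = 1.6
    ls_alphas: tuple = tuple(0.5**k for k in range(11))


@dataclass
class OptimalSolution:
    """Optimal inputs/states plus cost breakdown and solver diagnostics."""

    U: np.ndarray
    Z: np.ndarray
    cost: float
    breakdown: object
    trace: list = field(default_factory=list)
    converged: bool = False
    stalled: bool = False
    n_accepted: int = 0


# ---------------------------------------------------------------------------
# Problems
# ---------------------------------------------------------------------------


class _ProblemBase:
    """Shared rollout/linearization plumbing.

    Subclasses define the augmented state layout and provide ``step`` and
    ``linearize``.  Inputs always enter the first ``n_u`` state coordinates
    with constant gain ``input_gain = dt/tau``.
    """

    model: NetworkModel
    cost: object
    dt: float
    K: int
    n_z: int
    n_u: int
    z0: np.ndarray
    input_gain: float

    def rollout(self, U: np.ndarray) -> np.ndarray:
        Z = np.empty((self.K + 1, self.n_z))
        Z[0] = self.z0
        for k in range(self.K):
            Z[k + 1] = self.step(Z[k], U[k], k)
        return Z

    def total_cost(self, Z: np.ndarray, U: np.ndarray) -> float:
        return self.cost.total(Z, U)


class ReachProblem(_ProblemBase):
    """Network + two-link arm, augmented state z = [x (N); theta (2); omega (2)]."""

    def __init__(
        self,
        model: NetworkModel,
        arm: ArmParams,
        task: ControlTask,
        dt: float,
    ):
        if model.C is None or model.C.shape[0] != 2:
            raise ValueError("arm task requires a 2-output readout")
        self.model = model
        self.arm = arm
        self.task = task
        self.dt = dt
        cost_cls = SequenceCost if task.theta_star2 is not None else SingleReachCost
        self.cost = cost_cls(task, model, dt)
        self.K = self.cost.K
        self.n_u = model.n
        self.n_z = model.n + 4
        self.input_gain = dt / model.tau
        x0 = model.rest_rate if model.rest_rate is not None else np.zeros(model.n)
        theta0 = np.asarray(task.theta0, dtype=float).reshape(2)
        self.z0 = np.concatenate([x0, theta0, np.zeros(2)])

    def step(self, z: np.ndarray, u: np.ndarray, k: int) -> np.ndarray:
        N = self.model.n
        x, theta, omega = z[:N], z[N : N + 2], z[N + 2 :]
        h = self.model.h if self.model.h is not None else 0.0
        c = self.input_gain
        m = self.model.torque(self.model.phi(x))
        acc = arm_acceleration(theta, omega, m, self.arm)
        zn = np.empty_like(z)
        zn[:N] = x + c * (-x + self.model.W @ self.model.phi(x) + h + u)
        zn[N : N + 2] = theta + (self.dt * _MS) * omega
        zn[N + 2 :] = omega + (self.dt * _MS) * acc
        return zn

    def linearize(self, Z: np.ndarray, U: np.ndarray) -> np.ndarray:
        """State Jacobians F_k = df/dz along the trajectory, shape (K, n_z, n_z)."""
        N = self.model.n
        c = self.input_gain
        ds = self.dt * _MS
        W, C = self.model.W, self.model.C
        Fx = np.zeros((self.K, self.n_z, self.n_z))
        for k in range(self.K):
            z = Z[k]
            x, theta, omega = z[:N], z[N : N + 2], z[N + 2 :]
            d = self.model.phi_prime(x)
            m = self.model.torque(self.model.phi(x))
            F = Fx[k]
            F[:N, :N] = c * (W * d[None, :])
            F[:N, :N] += (1.0 - c) * np.eye(N)
            F[N : N + 2, N : N + 2] = np.eye(2)
            F[N : N + 2, N + 2 :] = ds * np.eye(2)
            d_th, d_om, d_m = arm_jacobians(theta, omega, m, self.arm)
            F[N + 2 :, :N] = ds * (d_m @ (C * d[None, :]))
            F[N + 2 :, N : N + 2] = ds * d_th
            F[N + 2 :, N + 2 :] = np.eye(2) + ds * d_om
        return Fx


class ToyProblem(_ProblemBase):
    """Two-unit network driving a 1D double integrator, z = [x (2); y; y_dot].

    The output acceleration is directly the 1D readout, y_dd = C x, so with
    the identity nonlinearity the whole problem is linear-quadratic and the
    optimizer converges in a single accepted iteration.
    """

    def __init__(self, model: NetworkModel, task: ControlTask, dt: float):
        if model.C is None or model.C.shape[0] != 1:
            raise ValueError("toy task requires a 1-output readout")
        self.model = model
        self.task = task
        self.dt = dt
        self.cost = ToyReachCost(task, model, dt)
        self.K = self.cost.K
        self.n_u = model.n
        self.n_z = model.n + 2
        self.input_gain = dt / model.tau
        self.z0 = np.zeros(self.n_z)
        self._Fx = self._build_jacobian()

    def _build_jacobian(self) -> np.ndarray:
        N = self.model.n
        c = self.input_gain
        ds = self.dt * _MS
        F = np.zeros((self.n_z, self.n_z))
        F[:N, :N] = (1.0 - c) * np.eye(N) + c * self.model.W
        F[N, N] = 1.0
        F[N, N + 1] = ds
        F[N + 1, :N] = ds * self.model.C[0]
        F[N + 1, N + 1] = 1.0
        return F

    def step(self, z: np.ndarray, u: np.ndarray, k: int) -> np.ndarray:
        zn = self._Fx @ z
        zn[: self.n_u] += self.input_gain * u
        return zn

    def linearize(self, Z: np.ndarray, U: np.ndarray) -> np.ndarray:
        return np.broadcast_to(self._Fx, (self.K, self.n_z, self.n_z))


def build_reach_problem(
    model: NetworkModel,
    effector: ArmParams | str,
    task: ControlTask,
    dt: float,
) -> _ProblemBase:
    """Assemble the augmented optimal-control problem.

    ``effector`` is an :class:`ArmParams` for the two-link arm task or the
    string ``"integrator"`` for the 1D toy task.
    """
    if isinstance(effector, ArmParams):
        return ReachProblem(model, effector, task, dt)
    if effector == "integrator":
        return ToyProblem(model, task, dt)
    raise ValueError("effector must be ArmParams or 'integrator'")


# ---------------------------------------------------------------------------
# Backward pass
# ---------------------------------------------------------------------------


def backward_pass(
    problem,
    Z: np.ndarray,
    U: np.ndarray,
    Fx: np.ndarray,
    mu: float,
):
    """One regularized Riccati sweep along (Z, U).

    Returns ``(k_ff, K_fb, dV1, dV2)`` — feedforward terms, feedback gains
    and the two expected-improvement coefficients — or ``None`` if the
    regularized control Hessian fails its Cholesky factorization at any
    step (the caller is expected to raise ``mu`` and retry).
    """
    from scipy.linalg import cho_factor, cho_solve

    K, n, m = problem.K, problem.n_z, problem.n_u
    g = problem.input_gain
    qN = problem.cost.quadratize_terminal(Z[K])
    Vx, Vxx = qN.lx.copy(), qN.lxx.copy()
    k_ff = np.empty((K, m))
    K_fb = np.empty((K, m, n))
    dV1 = 0.0
    dV2 = 0.0
    eye_m = np.eye(m)
    for k in range(K - 1, -1, -1):
        q = problem.cost.quadratize(Z[k], U[k], k)
        F = Fx[k]
        VF = Vxx @ F
        Qx = q.lx + F.T @ Vx
        Qu = q.lu + g * Vx[:m]
        Qxx = q.lxx + F.T @ VF
        Quu = q.luu + (g * g) * Vxx[:m, :m]
        Qux = q.lux + g * VF[:m, :]
        Quu_r = Quu + (g * g * mu) * eye_m
        Qux_r = Qux + (g * mu) * F[:m, :]
        try:
            cf = cho_factor(Quu_r, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return None
        kk = -cho_solve(cf, Qu, check_finite=False)
        KK = -cho_solve(cf, Qux_r, check_finite=False)
        k_ff[k] = kk
        K_fb[k] = KK
        Quu_kk = Quu @ kk
        Vx = Qx + KK.T @ (Quu_kk + Qu) + Qux.T @ kk
        Vxx = Qxx + KK.T @ (Quu @ KK) + KK.T @ Qux + Qux.T @ KK
        Vxx = 0.5 * (Vxx + Vxx.T)
        dV1 += float(kk @ Qu)
        dV2 += float(kk @ Quu_kk)
    return k_ff, K_fb, dV1, dV2


def _forward(problem, Z, U, k_ff, K_fb, alpha):
    """Feedback-controlled rollout at line-search step ``alpha``."""
    Zn = np.empty_like(Z)
    Un = np.empty_like(U)
    Zn[0] = Z[0]
    for k in range(problem.K):
        Un[k] = U[k] + alpha * k_ff[k] + K_fb[k] @ (Zn[k] - Z[k])
        Zn[k + 1] = problem.step(Zn[k], Un[k], k)
        if not np.all(np.isfinite(Zn[k + 1])):
            return None, None
    return Zn, Un


def input_gradient(problem, Z: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Gradient of the total cost w.r.t. the input trajectory (adjoint sweep)."""
    Fx = problem.linearize(Z, U)
    g = problem.input_gain
    m = problem.n_u
    qN = problem.cost.quadratize_terminal(Z[problem.K])
    lam = qN.lx.copy()
    grad = np.empty_like(U)
    for k in range(problem.K - 1, -1, -1):
        q = problem.cost.quadratize(Z[k], U[k], k)
        grad[k] = q.lu + g * lam[:m]
        lam = q.lx + Fx[k].T @ lam
    return grad


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------


def solve(
    problem,
    u_init: np.ndarray | None = None,
    options: ILQROptions = ILQROptions(),
) -> OptimalSolution:
    """Minimize the problem's cost functional over input trajectories.

    Deterministic given (problem, u_init, options).  Terminates when the
    expected improvement or the realized relative cost decrease falls below
    ``options.tol``, or when budgets are exhausted.  A failure to improve
    the cost at maximal regularization sets the ``stalled`` flag (with the
    best trajectory found); a rollout that diverges at every line-search
    step raises :class:`DivergenceError`.
    """
    U = (
        np.zeros((problem.K, problem.n_u))
        if u_init is None
        else np.asarray(u_init, dtype=float).copy()
    )
    if not np.all(np.isfinite(U)):
        raise ValueError("u_init must be finite")
    Z = problem.rollout(U)
    J = problem.total_cost(Z, U)
    mu = options.reg_init
    trace: list[dict] = []
    converged = False
    stalled = False
    n_accepted = 0
    for it in range(options.max_iter):
        Fx = problem.linearize(Z, U)
        bp = None
        while bp is None:
            bp = backward_pass(problem, Z, U, Fx, mu)
            if bp is None:
                mu = mu * options.reg_up if mu > 0 else options.reg_min
                if mu > options.reg_max:
                    stalled = True
                    break
        if stalled:
            break
        k_ff, K_fb, dV1, dV2 = bp
        expected_full = -(dV1 + 0.5 * dV2)
        if expected_full <= options.tol * (1.0 + abs(J)):
            converged = True
            break
        accepted = False
        diverged_all = True
        for alpha in options.ls_alphas:
            Zn, Un = _forward(problem, Z, U, k_ff, K_fb, alpha)
            if Zn is None:
                continue
            diverged_all = False
            Jn = problem.total_cost(Zn, Un)
            if np.isfinite(Jn) and Jn < J:
                expected = -(alpha * dV1 + 0.5 * alpha**2 * dV2)
                trace.append(
                    {
                        "iter": it,
                        "cost": Jn,
                        "prev_cost": J,
                        "reg": mu,
                        "alpha": alpha,
                        "expected": expected,
                        "actual": J - Jn,
                    }
                )
                rel = (J - Jn) / max(1.0, abs(J))
                Z, U, J = Zn, Un, Jn
                accepted = True
                n_accepted += 1
                mu = max(options.reg_min, mu / options.reg_down)
                if rel < options.tol:
                    converged = True
                break
        if diverged_all:
            raise DivergenceError("rollout non-finite at every line-search step")
        if not accepted:
            mu *= options.reg_up
            if mu > options.reg_max:
                stalled = True
                break
        if converged:
            break
    has_terms = hasattr(problem.cost, "breakdown")
    return OptimalSolution(
        U=U,
        Z=Z,
        cost=J,
        breakdown=problem.cost.breakdown(Z, U) if has_terms else None,
        trace=trace,
        converged=converged,
        stalled=stalled,
        n_accepted=n_accepted,
    )
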