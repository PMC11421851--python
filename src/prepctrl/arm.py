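"""Two-link planar arm: kinematics, rigid-body dynamics, and their Jacobians.

The effector is the standard planar two-joint arm used in reach-control
models: shoulder at the origin, upper arm of length ``L1``, forearm of length
``L2``, driven by a pair of joint torques ``m`` (N·m).  The joint state is
``theta = (theta1, theta2)`` (shoulder and elbow angles, rad) and its
velocity ``omega``.  The equation of motion is

    m = M(theta) theta_dd + X(theta, omega) + B omega

with inertia matrix ``M``, centripetal/Coriolis vector ``X`` and a constant
joint-friction matrix ``B``.  There is no gravity term (planar model) and no
joint limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArmParams",
    "ArmState",
    "OutOfWorkspaceError",
    "forward_kinematics",
    "inverse_kinematics",
    "hand_jacobian",
    "inertia_matrix",
    "coriolis_vector",
    "arm_acceleration",
    "arm_jacobians",
]


class OutOfWorkspaceError(ValueError):
    """Raised when a Cartesian target lies outside the reachable annulus."""


def _default_friction() -> np.ndarray:
    return np.array([[0.05, 0.025], [0.025, 0.05]])


@dataclass(frozen=True)
class ArmParams:
    """Physical parameters of the two-link arm (SI units).

    Defaults follow the standard parameterization used in planar-reaching
    models: 30 cm links, upper-arm mass 1.4 kg, forearm mass 1.0 kg,
    inertias 0.025 / 0.045 kg·m², forearm center of mass 16 cm from the
    elbow, and symmetric joint friction.
    """

    L1: float = 0.30
    L2: float = 0.30
    M1: float = 1.4
    M2: float = 1.0
    I1: float = 0.025
    I2: float = 0.045
    D2: float = 0.16
    B: np.ndarray = field(default_factory=_default_friction)

    def __post_init__(self) -> None:
        for name in ("L1", "L2", "M1", "M2", "I1", "I2", "D2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        B = np.asarray(self.B, dtype=float)
        if B.shape != (2, 2) or not np.allclose(B, B.T):
            raise ValueError("friction matrix B must be symmetric 2x2")
        if np.any(np.linalg.eigvalsh(B) < -1e-12):
            raise ValueError("friction matrix B must be positive semidefinite")
        object.__setattr__(self, "B", B)

    # inertia coefficients a1, a2, a3 of M(theta)
    @property
    def a1(self) -> float:
        return self.I1 + self.I2 + self.M2 * self.L1**2

    @property
    def a2(self) -> float:
        return self.M2 * self.L1 * self.D2

    @property
    def a3(self) -> float:
        return self.I2


@dataclass
class ArmState:
    """Joint angles (rad) and angular velocities (rad/s)."""

    theta: np.ndarray
    omega: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float).reshape(2)
        self.omega = np.asarray(self.omega, dtype=float).reshape(2)
        if not (np.all(np.isfinite(self.theta)) and np.all(np.isfinite(self.omega))):
            raise ValueError("arm state must be finite")


def forward_kinematics(
    theta: np.ndarray, params: ArmParams = ArmParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Hand and elbow position (m) in shoulder-centered coordinates."""
    t1, t2 = np.asarray(theta, dtype=float).reshape(2)
    elbow = np.array([params.L1 * np.cos(t1), params.L1 * np.sin(t1)])
    hand = elbow + np.array(
        [params.L2 * np.cos(t1 + t2), params.L2 * np.sin(t1 + t2)]
    )
    return hand, elbow


def hand_jacobian(theta: np.ndarray, params: ArmParams = ArmParams()) -> np.ndarray:
    """2x2 Jacobian d(hand position)/d(theta); hand velocity is J @ omega."""
    t1, t2 = np.asarray(theta, dtype=float).reshape(2)
    s1, c1 = np.sin(t1), np.cos(t1)
    s12, c12 = np.sin(t1 + t2), np.cos(t1 + t2)
    return np.array(
        [
            [-params.L1 * s1 - params.L2 * s12, -params.L2 * s12],
            [params.L1 * c1 + params.L2 * c12, params.L2 * c12],
        ]
    )


def inverse_kinematics(
    hand_target: np.ndarray,
    params: ArmParams = ArmParams(),
    branch: str = "down",
) -> np.ndarray:
    """Joint angles reaching ``hand_target``; ``branch`` picks the elbow sign.

    ``branch='down'`` returns the elbow-down solution (theta2 <= 0),
    ``branch='up'`` the mirror solution.  Raises
    :class:`OutOfWorkspaceError` for targets outside the reachable annulus
    ``|L1 - L2| <= |p| <= L1 + L2`` (or at the origin).
    """
    if branch not in ("down", "up"):
        raise ValueError("branch must be 'down' or 'up'")
    p = np.asarray(hand_target, dtype=float).reshape(2)
    d2 = float(p @ p)
    d = np.sqrt(d2)
    lo, hi = abs(params.L1 - params.L2), params.L1 + params.L2
    if d == 0.0 or d < lo - 1e-12 or d > hi + 1e-12:
        raise OutOfWorkspaceError(
            f"target at distance {d:.4f} m outside reachable annulus [{lo}, {hi}]"
        )
    c2 = (d2 - params.L1**2 - params.L2**2) / (2 * params.L1 * params.L2)
    c2 = np.clip(c2, -1.0, 1.0)
    t2 = np.arccos(c2)
    if branch == "down":
        t2 = -t2
    t1 = np.arctan2(p[1], p[0]) - np.arctan2(
        params.L2 * np.sin(t2), params.L1 + params.L2 * np.cos(t2)
    )
    return np.array([t1, t2])


def inertia_matrix(theta: np.ndarray, params: ArmParams = ArmParams()) -> np.ndarray:
    """Configuration-dependent inertia M(theta) (depends on theta2 only)."""
    c2 = np.cos(np.asarray(theta, dtype=float).reshape(2)[1])
    a1, a2, a3 = params.a1, params.a2, params.a3
    return np.array([[a1 + 2 * a2 * c2, a3 + a2 * c2], [a3 + a2 * c2, a3]])


def coriolis_vector(
    theta: np.ndarray, omega: np.ndarray, params: ArmParams = ArmParams()
) -> np.ndarray:
    """Centripetal/Coriolis torques X(theta, omega)."""
    t2 = np.asarray(theta, dtype=float).reshape(2)[1]
    w1, w2 = np.asarray(omega, dtype=float).reshape(2)
    return params.a2 * np.sin(t2) * np.array([-w2 * (2 * w1 + w2), w1**2])


def arm_acceleration(
    theta: np.ndarray,
    omega: np.ndarray,
    m: np.ndarray,
    params: ArmParams = ArmParams(),
) -> np.ndarray:
    """Angular acceleration M(theta)^-1 (m - X(theta, omega) - B omega)."""
    M = inertia_matrix(theta, params)
    X = coriolis_vector(theta, omega, params)
    rhs = np.asarray(m, dtype=float).reshape(2) - X - params.B @ np.asarray(
        omega, dtype=float
    ).reshape(2)
    return np.linalg.solve(M, rhs)


def arm_jacobians(
    theta: np.ndarray,
    omega: np.ndarray,
    m: np.ndarray,
    params: ArmParams = ArmParams(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic partials of the acceleration w.r.t. (theta, omega, m).

    Returns ``(d_theta, d_omega, d_m)``, each 2x2.  Only theta2 enters the
    dynamics, so the first column of ``d_theta`` is zero.
    """
    theta = np.asarray(theta, dtype=float).reshape(2)
    omega = np.asarray(omega, dtype=float).reshape(2)
    t2 = theta[1]
    w1, w2 = omega
    a2 = params.a2
    s2, c2 = np.sin(t2), np.cos(t2)

    M = inertia_matrix(theta, params)
    Minv = np.linalg.inv(M)
    acc = arm_acceleration(theta, omega, m, params)

    dM_dt2 = np.array([[-2 * a2 * s2, -a2 * s2], [-a2 * s2, 0.0]])
    dX_dt2 = a2 * c2 * np.array([-w2 * (2 * w1 + w2), w1**2])
    # d acc / d theta2 = M^-1 (-dX/dt2 - dM/dt2 @ acc)
    dacc_dt2 = Minv @ (-dX_dt2 - dM_dt2 @ acc)
    d_theta = np.zeros((2, 2))
    d_theta[:, 1] = dacc_dt2

    dX_dw = a2 * s2 * np.array([[-2 * w2, -2 * w1 - 2 * w2], [2 * w1, 0.0]])
    d_omega = Minv @ (-dX_dw - params.B)
    d_m = Minv
    return d_theta, d_omega, d_m
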