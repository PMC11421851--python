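"""Orthogonal preparatory/movement subspaces and occupancy time courses.

Trial-averaged population activity during delayed reaches segregates into
two low-dimensional subspaces: one occupied before movement onset
(preparatory) and one during the movement itself.  Following the standard
analysis, the two bases are found jointly by maximizing the normalized
captured variance

    C(W_prep, W_mov) = 1/2 ( Tr(W_prep^T C_prep W_prep) / Z_prep(d_prep)
                           + Tr(W_mov^T  C_mov  W_mov)  / Z_mov(d_mov) )

subject to W_prep^T W_mov = 0 and each basis being orthonormal, where
C_prep / C_mov are epoch covariance matrices and Z(d) is the variance the
best unconstrained d-dimensional subspace would capture (top-d eigenvalue
sum).  The constrained maximization runs as projected gradient ascent on
the joint orthonormal frame [W_prep, W_mov] (QR retraction, multi-start).

Occupancy of a basis at time t is the across-condition variance of the
projected activity summed over basis dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SubspacePair",
    "EpochActivity",
    "normalize_rates",
    "identify_subspaces",
    "occupancy",
    "movement_onset",
]


@dataclass
class SubspacePair:
    """Orthonormal preparatory and movement bases with fit diagnostics."""

    W_prep: np.ndarray  # (N, d_prep)
    W_mov: np.ndarray  # (N, d_mov)
    Z_prep: float
    Z_mov: float
    objective: float
    var_frac_prep: float  # captured / total variance, preparatory epoch
    var_frac_mov: float
    converged: bool = True

    def constraint_residual(self) -> float:
        r1 = np.linalg.norm(self.W_prep.T @ self.W_prep - np.eye(self.W_prep.shape[1]))
        r2 = np.linalg.norm(self.W_mov.T @ self.W_mov - np.eye(self.W_mov.shape[1]))
        r3 = np.linalg.norm(self.W_prep.T @ self.W_mov)
        return max(r1, r2, r3)


@dataclass
class EpochActivity:
    """Trial-averaged normalized rates for the two epochs.

    ``prep`` and ``mov`` are N x (M * T_bins) matrices (conditions and time
    bins concatenated).  Default windows: preparatory = the 300 ms before
    delay end, movement = 300 ms starting 50 ms after the go cue.
    """

    prep: np.ndarray
    mov: np.ndarray


def normalize_rates(rates: np.ndarray, soft: float = 5.0, center: bool = True) -> np.ndarray:
    """Soft-normalize and (optionally) center trial-averaged rates.

    ``rates`` has shape (N, M, T) — neurons x conditions x time bins.  Each
    neuron's traces are divided by (range over all conditions/times + soft)
    so high-rate neurons do not dominate; the across-condition mean at each
    time is then subtracted.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.ndim != 3:
        raise ValueError("rates must be (neurons, conditions, time)")
    rng = rates.max(axis=(1, 2)) - rates.min(axis=(1, 2))
    out = rates / (rng + soft)[:, None, None]
    if center:
        out = out - out.mean(axis=1, keepdims=True)
    return out


def _top_eigsum(Cmat: np.ndarray, d: int) -> float:
    evals = np.linalg.eigvalsh(Cmat)
    return float(evals[-d:].sum())


def _objective(U: np.ndarray, C1: np.ndarray, C2: np.ndarray, d1: int, z1: float, z2: float) -> float:
    W1, W2 = U[:, :d1], U[:, d1:]
    return 0.5 * (
        float(np.trace(W1.T @ C1 @ W1)) / z1 + float(np.trace(W2.T @ C2 @ W2)) / z2
    )


def identify_subspaces(
    epochs: EpochActivity,
    d_prep: int = 6,
    d_mov: int = 6,
    n_restarts: int = 10,
    max_iter: int = 2000,
    tol: float = 1e-12,
    seed: int = 0,
) -> SubspacePair:
    """Jointly fit orthogonal preparatory and movement subspaces.

    Gradient ascent on the combined N x (d_prep + d_mov) orthonormal frame
    with QR retraction and adaptive step size; the first start is the
    spectral initialization (top eigenvectors of each epoch covariance,
    orthogonalized), followed by ``n_restarts`` random orthonormal starts.
    The best objective over starts is kept.
    """
    Xp, Xm = np.asarray(epochs.prep, float), np.asarray(epochs.mov, float)
    N = Xp.shape[0]
    if Xm.shape[0] != N:
        raise ValueError("epochs must have the same neuron count")
    if d_prep + d_mov > N:
        raise ValueError("d_prep + d_mov must not exceed the neuron count")
    C1 = Xp @ Xp.T / max(Xp.shape[1] - 1, 1)
    C2 = Xm @ Xm.T / max(Xm.shape[1] - 1, 1)
    z1, z2 = _top_eigsum(C1, d_prep), _top_eigsum(C2, d_mov)
    if z1 <= 0 or z2 <= 0:
        raise ValueError("epoch activity has no variance")
    d = d_prep + d_mov
    rng = np.random.default_rng(seed)

    def _spectral_start() -> np.ndarray:
        _, v1 = np.linalg.eigh(C1)
        _, v2 = np.linalg.eigh(C2)
        U0 = np.concatenate([v1[:, -d_prep:], v2[:, -d_mov:]], axis=1)
        q, _ = np.linalg.qr(U0)
        return q[:, :d]

    best = None
    best_f = -np.inf
    starts = [_spectral_start()] + [
        np.linalg.qr(rng.standard_normal((N, d)))[0] for _ in range(n_restarts)
    ]
    any_converged = False
    for U in starts:
        eta = 0.1
        f = _objective(U, C1, C2, d_prep, z1, z2)
        converged = False
        for _ in range(max_iter):
            G = np.concatenate(
                [C1 @ U[:, :d_prep] / z1, C2 @ U[:, d_prep:] / z2], axis=1
            )
            # tangent projection for the Stiefel manifold
            UtG = U.T @ G
            G_t = G - U @ (0.5 * (UtG + UtG.T))
            Un, _ = np.linalg.qr(U + eta * G_t)
            # fix QR sign ambiguity for a continuous ascent path
            Un *= np.sign(np.sum(Un * U, axis=0))[None, :]
            fn = _objective(Un, C1, C2, d_prep, z1, z2)
            if fn > f:
                if fn - f < tol * max(1.0, abs(f)):
                    U, f = Un, fn
                    converged = True
                    break
                U, f = Un, fn
                eta = min(eta * 1.2, 10.0)
            else:
                eta *= 0.5
                if eta < 1e-12:
                    converged = True
                    break
        any_converged = any_converged or converged
        if f > best_f:
            best_f, best = f, U
    W1, W2 = best[:, :d_prep], best[:, d_prep:]
    return SubspacePair(
        W_prep=W1,
        W_mov=W2,
        Z_prep=z1,
        Z_mov=z2,
        objective=best_f,
        var_frac_prep=float(np.trace(W1.T @ C1 @ W1) / np.trace(C1)),
        var_frac_mov=float(np.trace(W2.T @ C2 @ W2) / np.trace(C2)),
        converged=any_converged,
    )


def occupancy(
    activity: np.ndarray, basis: np.ndarray, normalize: bool = False
) -> np.ndarray:
    """Across-condition variance of projected activity, summed over basis
    dimensions, per time bin.

    ``activity`` has shape (N, M, T); ``basis`` is an (N, d) orthonormal
    matrix.  With a single condition the curve is identically zero.  If
    ``normalize`` the curve is scaled to a maximum of 1.
    """
    activity = np.asarray(activity, dtype=float)
    proj = np.einsum("nd,nmt->dmt", np.asarray(basis, float), activity)
    occ = proj.var(axis=1, ddof=0).sum(axis=0)
    if normalize and occ.max() > 0:
        occ = occ / occ.max()
    return occ


def movement_onset(
    speed: np.ndarray,
    dt: float,
    threshold: float | None = None,
    lag: float = 120.0,
    t0: float = 0.0,
) -> float:
    """Movement-onset time: first threshold crossing of the hand speed plus
    a fixed lag (default 120 ms, mimicking cortico-spinal conduction and
    muscle inertia).

    ``speed`` is sampled every ``dt`` ms starting at time ``t0``; the
    default threshold is 5% of the peak speed.  Raises ``ValueError`` if
    the speed never crosses the threshold.
    """
    speed = np.asarray(speed, dtype=float)
    if threshold is None:
        threshold = 0.05 * float(speed.max())
    idx = np.nonzero(speed >= threshold)[0]
    if idx.size == 0:
        raise ValueError("speed never crosses the threshold")
    return t0 + dt * float(idx[0]) + lag
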