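"""Preparation index and Gramian-based predictors of preparation.

The preparation index of an optimally controlled reach is the ratio of
integrated squared input norm during the delay epoch to that during the
movement epoch.  Two control-theoretic summaries of a linearized network
``dx/dt = A x + u``, ``y = C x`` (with ``A = (-I + W)/tau``) predict it:

* ``alpha`` — observability of the readout nullspace: how much output
  energy a unit initial condition confined to the output-null subspace
  eventually generates, ``Tr(C_perp Q C_perp^T) / (N - k)`` with Q the
  observability Gramian;
* ``beta`` — controllability of the readout: how much variance isotropic
  input noise induces along the readout rows, ``Tr(C P C^T) / k`` with P
  the controllability Gramian (unit input weights, B = I).

A cross-validated linear model ``prep_index ~ k0 + ka*alpha + kb*beta`` (on
z-scored predictors) quantifies how much of the across-network variation in
preparation these two numbers explain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import null_space, solve_continuous_lyapunov
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold, cross_val_predict

__all__ = [
    "UndefinedIndexError",
    "UnstableSystemError",
    "GramianSummary",
    "PrepPrediction",
    "preparation_index",
    "observability_gramian",
    "controllability_gramian",
    "nullspace_basis",
    "alpha",
    "beta",
    "gramian_summary",
    "fit_prep_predictor",
]


class UndefinedIndexError(ZeroDivisionError):
    """Movement-epoch input energy is zero: the preparation index is undefined."""


class UnstableSystemError(ValueError):
    """Gramians require a Hurwitz dynamics matrix."""


@dataclass(frozen=True)
class GramianSummary:
    """Per-network nullspace observability and readout controllability."""

    alpha: float
    beta: float
    n: int
    n_outputs: int


@dataclass
class PrepPrediction:
    """Cross-validated linear prediction of the preparation index."""

    intercept: float
    k_alpha: float
    k_beta: float
    r2_cv: float
    r2_alpha_only: float
    r2_beta_only: float
    zscore_mean: np.ndarray
    zscore_std: np.ndarray
    records: pd.DataFrame


def preparation_index(
    U: np.ndarray, times: np.ndarray | None = None, delay: float | None = None,
    dt: float | None = None,
) -> float:
    """Ratio of delay-epoch to movement-epoch integrated squared input norm.

    ``U`` has one input sample per time step.  Pass either the per-step
    ``times`` (sample k applies on [t_k, t_k + dt)) or ``delay`` and ``dt``.
    Steps with t < 0 belong to the delay epoch; the go-cue sample t = 0
    belongs to the movement epoch.  The dt factors cancel in the ratio.
    """
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if times is None:
        if delay is None or dt is None:
            raise ValueError("pass times, or delay and dt")
        times = -delay + dt * np.arange(U.shape[0])
    times = np.asarray(times, dtype=float)[: U.shape[0]]
    energy = np.sum(U**2, axis=1)
    num = float(energy[times < -1e-9].sum())
    den = float(energy[times >= -1e-9].sum())
    if den == 0.0:
        raise UndefinedIndexError("movement-epoch input energy is zero")
    return num / den


def _check_hurwitz(A: np.ndarray) -> None:
    if np.max(np.linalg.eigvals(A).real) >= 0:
        raise UnstableSystemError("dynamics matrix must be Hurwitz")


def observability_gramian(A: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Solve A^T Q + Q A + C^T C = 0 (symmetric PSD solution)."""
    A = np.asarray(A, dtype=float)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    _check_hurwitz(A)
    Q = solve_continuous_lyapunov(A.T, -C.T @ C)
    return 0.5 * (Q + Q.T)


def controllability_gramian(A: np.ndarray, B: np.ndarray | None = None) -> np.ndarray:
    """Solve A P + P A^T + B B^T = 0; inputs enter every unit (B = I) by default."""
    A = np.asarray(A, dtype=float)
    _check_hurwitz(A)
    BBt = np.eye(A.shape[0]) if B is None else np.asarray(B) @ np.asarray(B).T
    P = solve_continuous_lyapunov(A, -BBt)
    return 0.5 * (P + P.T)


def nullspace_basis(C: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the readout nullspace, shape (N - k, N)."""
    C = np.atleast_2d(np.asarray(C, dtype=float))
    k, n = C.shape
    if np.linalg.matrix_rank(C) < k:
        raise ValueError("readout matrix must have full row rank")
    return null_space(C).T


def alpha(A: np.ndarray, C: np.ndarray) -> float:
    """Nullspace observability Tr(C_perp Q C_perp^T) / (N - k)."""
    C = np.atleast_2d(np.asarray(C, dtype=float))
    Cp = nullspace_basis(C)
    Q = observability_gramian(A, C)
    return float(np.trace(Cp @ Q @ Cp.T)) / (C.shape[1] - C.shape[0])


def beta(A: np.ndarray, C: np.ndarray) -> float:
    """Readout controllability Tr(C P C^T) / k."""
    C = np.atleast_2d(np.asarray(C, dtype=float))
    P = controllability_gramian(A)
    return float(np.trace(C @ P @ C.T)) / C.shape[0]


def gramian_summary(model) -> GramianSummary:
    """alpha/beta of a network's linearization A = (-I + W)/tau.

    Controllability and observability are linear-systems notions, so the
    identity nonlinearity is used here regardless of the model's ``phi``.
    """
    A = model.jacobian()
    C = np.atleast_2d(model.C)
    return GramianSummary(
        alpha=alpha(A, C), beta=beta(A, C), n=model.n, n_outputs=C.shape[0]
    )


def fit_prep_predictor(records: pd.DataFrame, folds: int = 5, seed: int = 0) -> PrepPrediction:
    """Fit prep_index ~ k0 + ka*alpha + kb*beta with k-fold cross-validation.

    ``records`` must contain columns ``alpha``, ``beta`` and ``prep_index``.
    Predictors are z-scored before fitting; the reported R² values are
    cross-validated (default fivefold), for the two-predictor model and for
    each single-predictor ablation.
    """
    if len(records) < 2 * folds:
        raise ValueError("need at least 2*folds records")
    X = records[["alpha", "beta"]].to_numpy(dtype=float)
    y = records["prep_index"].to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    if np.any(sd == 0) or y.std() == 0:
        raise ValueError("degenerate (constant) predictor or response")
    Xz = (X - mu) / sd

    def _cv_r2(Xcols: np.ndarray) -> float:
        cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
        pred = cross_val_predict(LinearRegression(), Xcols, y, cv=cv)
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - ss_res / ss_tot

    fit = LinearRegression().fit(Xz, y)
    out = records.copy()
    out["prep_index_fit"] = fit.predict(Xz)
    return PrepPrediction(
        intercept=float(fit.intercept_),
        k_alpha=float(fit.coef_[0]),
        k_beta=float(fit.coef_[1]),
        r2_cv=_cv_r2(Xz),
        r2_alpha_only=_cv_r2(Xz[:, [0]]),
        r2_beta_only=_cv_r2(Xz[:, [1]]),
        zscore_mean=mu,
        zscore_std=sd,
        records=out,
    )
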