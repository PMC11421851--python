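"""Neural plants: recurrent rate networks, readouts, baselines, simulation.

All models share the rate dynamics

    tau dx/dt = -x + W phi(x) + h + u(t),      r = phi(x),      m = C r

with a rectified-linear or identity nonlinearity phi.  Three families are
provided:

* inhibition-stabilized networks (ISNs): sparse, log-normal excitatory
  weights obeying Dale's law, with the inhibitory weights iteratively
  adjusted by gradient descent on the H2 norm of a shifted linearization
  until the spectral abscissa of W falls below a target (default 0.8);
* two-unit motifs isolating the canonical dynamical phenomena of E/I
  circuits: a feedforward ("nonnormal") source->sink motif and an
  antisymmetric oscillatory motif;
* unstructured ensembles (random Gaussian, skew-symmetric, diagonally
  shifted skew-symmetric) used to probe the generality of Gramian-based
  predictors of preparation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.linalg import solve_continuous_lyapunov

__all__ = [
    "NetworkModel",
    "EnsembleSpec",
    "StabilizationError",
    "SimulationDivergenceError",
    "generate_isn",
    "generate_2d",
    "generate_ensemble",
    "generate_readout",
    "set_baseline",
    "simulate",
    "spectral_abscissa",
    "save_network",
    "load_network",
]

Nonlinearity = Literal["relu", "identity"]


class StabilizationError(RuntimeError):
    """Inhibitory optimization failed to reach the target spectral abscissa."""

    def __init__(self, abscissa: float, iterations: int):
        self.abscissa = abscissa
        self.iterations = iterations
        super().__init__(
            f"stabilization stopped at spectral abscissa {abscissa:.4f} "
            f"after {iterations} iterations"
        )


class SimulationDivergenceError(RuntimeError):
    """Euler integration produced a non-finite state."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"state became non-finite at step {step}")


@dataclass
class NetworkModel:
    """A recurrent rate network with optional readout and baseline input.

    Attributes
    ----------
    W : (N, N) recurrent weight matrix (dimensionless).
    C : (k, N) readout mapping rates (Hz) to torques (N·m), or None.
    h : (N,) baseline input, or None (treated as zero).
    tau : single-neuron time constant, ms.
    nonlinearity : "relu" (rates are rectified activations) or "identity".
    exc : indices of excitatory neurons (ISNs only).
    inh : indices of inhibitory neurons (ISNs only).
    """

    W: np.ndarray
    C: np.ndarray | None = None
    h: np.ndarray | None = None
    tau: float = 150.0
    nonlinearity: Nonlinearity = "relu"
    family: str = "custom"
    seed: int | None = None
    exc: np.ndarray | None = None
    inh: np.ndarray | None = None
    rest_rate: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("W must be finite")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.nonlinearity not in ("relu", "identity"):
            raise ValueError("nonlinearity must be 'relu' or 'identity'")

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def phi(self, x: np.ndarray) -> np.ndarray:
        if self.nonlinearity == "relu":
            return np.maximum(x, 0.0)
        return x

    def phi_prime(self, x: np.ndarray) -> np.ndarray:
        """Derivative of the nonlinearity; the kink at 0 uses the inactive side."""
        if self.nonlinearity == "relu":
            return (x > 0.0).astype(float)
        return np.ones_like(x)

    def jacobian(self) -> np.ndarray:
        """Linearized continuous-time dynamics matrix A = (-I + W)/tau (1/ms)."""
        return (-np.eye(self.n) + self.W) / self.tau

    def torque(self, r: np.ndarray) -> np.ndarray:
        """Readout m = C (r - r*), with r* the baseline rates (zero if unset).

        Torques are driven by rate deviations around baseline so that the
        resting state is an equilibrium of the coupled network+arm system
        (otherwise the constant baseline readout would push the arm before
        target onset).
        """
        if self.C is None:
            raise ValueError("model has no readout")
        rest = self.rest_rate if self.rest_rate is not None else 0.0
        dev = r - rest
        return dev @ self.C.T if dev.ndim > 1 else self.C @ dev


@dataclass(frozen=True)
class EnsembleSpec:
    """Specification of one network from an unstructured ensemble."""

    family: Literal["random", "skew", "shifted-skew"]
    scale: float
    n: int
    seed: int
    shift: float = 0.0  # lambda, shifted-skew only

    def __post_init__(self) -> None:
        if self.family == "random" and not 0.0 <= self.scale <= 0.99:
            raise ValueError("random ensemble radius must lie in [0, 0.99]")
        if self.family == "skew" and not 0.0 <= self.scale <= 5.0:
            raise ValueError("skew ensemble radius must lie in [0, 5]")
        if self.family == "shifted-skew" and not 0.0 <= self.shift <= 0.8:
            raise ValueError("shifted-skew lambda must lie in [0, 0.8]")


def spectral_abscissa(W: np.ndarray) -> float:
    """Maximum real part of the eigenvalues of W."""
    return float(np.max(np.linalg.eigvals(W).real))


# ---------------------------------------------------------------------------
# ISN generation
# ---------------------------------------------------------------------------


def _h2_sq(W: np.ndarray, shift: float) -> float:
    """Squared H2 norm (= Tr Q) of dx/dt = (W - shift I) x + u, with B=C=I."""
    n = W.shape[0]
    A = W - shift * np.eye(n)
    Q = solve_continuous_lyapunov(A.T, -np.eye(n))
    return float(np.trace(Q))


def stabilize_inhibition(
    W: np.ndarray,
    inh_mask: np.ndarray,
    target: float = 0.8,
    margin: float = 0.1,
    max_iter: int = 6000,
    eta0: float = 1e-3,
    return_log: bool = False,
) -> np.ndarray | tuple[np.ndarray, list[dict]]:
    """Reduce the spectral abscissa of W below ``target`` by adjusting
    inhibitory weights.

    Gradient descent on the squared H2 norm of the shifted system
    ``A = W - s I`` (with ``s`` just above the current abscissa so that A is
    Hurwitz), restricted to the entries flagged in ``inh_mask`` and projected
    to remain nonpositive.  The gradient of Tr(Q) w.r.t. A is ``2 Q P`` with
    Q, P the observability/controllability Gramians of (A, I, I); a
    backtracking line search guarantees a monotone decrease of the objective
    at fixed shift.
    """
    W = W.copy()
    n = W.shape[0]
    eye = np.eye(n)
    a = spectral_abscissa(W)
    eta = eta0
    log: list[dict] = []
    for it in range(max_iter):
        if a < target:
            break
        s = a + margin
        A = W - s * eye
        Q = solve_continuous_lyapunov(A.T, -eye)
        P = solve_continuous_lyapunov(A, -eye)
        f = float(np.trace(Q))
        G = 2.0 * (Q @ P)
        G = np.where(inh_mask, G, 0.0)
        gnorm = float(np.linalg.norm(G))
        if gnorm == 0.0:
            raise StabilizationError(a, it)
        accepted = False
        for _ in range(50):
            Wn = W - eta * G
            Wn = np.where(inh_mask, np.minimum(Wn, 0.0), Wn)
            an = spectral_abscissa(Wn)
            if an < s:  # shifted system still stable -> objective defined
                fn = _h2_sq(Wn, s)
                if fn < f:
                    accepted = True
                    break
            eta *= 0.5
        if not accepted:
            raise StabilizationError(a, it)
        W, a = Wn, an
        log.append(
            {
                "iter": it,
                "abscissa": a,
                "h2_sq_before": f,
                "h2_sq": fn,
                "eta": eta,
                "shift": s,
            }
        )
        eta *= 1.5
    else:
        raise StabilizationError(a, max_iter)
    if return_log:
        return W, log
    return W


def generate_isn(
    n: int = 200,
    exc_scale: float = 2.5,
    target_abscissa: float = 0.8,
    seed: int = 0,
    p_exc: float = 0.8,
    p_con_exc: float = 0.2,
    p_con_inh: float = 0.4,
    sigma_ln: float = 1.0,
    tau: float = 150.0,
    max_iter: int = 6000,
) -> NetworkModel:
    """Generate an inhibition-stabilized network obeying Dale's law.

    Excitatory columns are sparse (connection probability ``p_con_exc``)
    with log-normally distributed positive weights whose overall strength is
    set by ``exc_scale`` (the matrix is rescaled so the *initial* spectral
    abscissa equals ``exc_scale``, i.e. the unstabilized network sits well
    beyond the stability line).  Inhibitory columns are denser and
    initialized to balance the mean excitatory input per row; they are then
    optimized by :func:`stabilize_inhibition` until the spectral abscissa of
    W falls below ``target_abscissa``.
    """
    if n < 10:
        raise ValueError("n must be at least 10")
    if not target_abscissa < 1.0:
        raise ValueError("target spectral abscissa must be < 1")
    rng = np.random.default_rng(seed)
    n_e = int(round(p_exc * n))
    exc = np.arange(n_e)
    inh = np.arange(n_e, n)

    # sparse log-normal E weights, mean-one shape times a 1/sqrt(n) scale
    mask_e = rng.random((n, n_e)) < p_con_exc
    w_e = np.exp(sigma_ln * rng.standard_normal((n, n_e)) - sigma_ln**2 / 2)
    We = np.where(mask_e, w_e, 0.0) / np.sqrt(n)

    # dense-ish I weights balancing the mean E input per row
    mask_i = rng.random((n, n - n_e)) < p_con_inh
    w_i = np.exp(sigma_ln * rng.standard_normal((n, n - n_e)) - sigma_ln**2 / 2)
    mean_e_in = We.sum(axis=1).mean()
    n_i_con = max(p_con_inh * (n - n_e), 1.0)
    Wi = -np.where(mask_i, w_i, 0.0) * (mean_e_in / n_i_con)

    W = np.concatenate([We, Wi], axis=1)
    np.fill_diagonal(W, 0.0)
    a0 = spectral_abscissa(W)
    if exc_scale > 0 and a0 > 0:
        W *= exc_scale / a0
    elif exc_scale == 0:
        W[:] = 0.0

    inh_mask = np.zeros((n, n), dtype=bool)
    inh_mask[:, inh] = W[:, inh] < 0  # optimize existing I connections only
    np.fill_diagonal(inh_mask, False)

    log: list[dict] = []
    if spectral_abscissa(W) >= target_abscissa:
        W, log = stabilize_inhibition(
            W, inh_mask, target=target_abscissa, max_iter=max_iter, return_log=True
        )
    return NetworkModel(
        W=W,
        tau=tau,
        nonlinearity="relu",
        family="isn",
        seed=seed,
        exc=exc,
        inh=inh,
        meta={
            "exc_scale": exc_scale,
            "target_abscissa": target_abscissa,
            "stabilization_iters": len(log),
            "stabilization_log": log,
        },
    )


# ---------------------------------------------------------------------------
# Two-unit motifs and unstructured ensembles
# ---------------------------------------------------------------------------


def generate_2d(kind: str, w: float, tau: float = 150.0) -> NetworkModel:
    """Two-unit motif: ``feedforward`` (source unit 0 drives sink unit 1)
    or ``oscillatory`` (antisymmetric rotation), with identity nonlinearity."""
    if w < 0:
        raise ValueError("w must be nonnegative")
    if kind == "feedforward":
        W = np.array([[0.0, 0.0], [w, 0.0]])
    elif kind == "oscillatory":
        W = np.array([[0.0, -w], [w, 0.0]])
    else:
        raise ValueError("kind must be 'feedforward' or 'oscillatory'")
    return NetworkModel(
        W=W, tau=tau, nonlinearity="identity", family=kind, meta={"w": w}
    )


def generate_ensemble(spec: EnsembleSpec, tau: float = 150.0) -> NetworkModel:
    """Draw one network from an unstructured ensemble.

    ``random``: i.i.d. Gaussian entries with s.d. R/sqrt(N) so the
    circular-law spectral radius equals R.  ``skew``: W = (S - S^T)/2 for a
    random S (purely imaginary spectrum).  ``shifted-skew``: the same plus
    ``shift`` times the identity (all eigenvalues have real part ``shift``).
    """
    rng = np.random.default_rng(spec.seed)
    S = rng.standard_normal((spec.n, spec.n)) * (spec.scale / np.sqrt(spec.n))
    if spec.family == "random":
        W = S
    else:
        W = (S - S.T) / 2.0
        if spec.family == "shifted-skew":
            W = W + spec.shift * np.eye(spec.n)
    return NetworkModel(
        W=W,
        tau=tau,
        nonlinearity="relu",
        family=spec.family,
        seed=spec.seed,
        meta={"scale": spec.scale, "shift": spec.shift},
    )


def generate_readout(
    n: int,
    n_outputs: int = 2,
    seed: int = 0,
    scale: float | None = None,
    convention: Literal["sqrt", "literal"] = "sqrt",
) -> np.ndarray:
    """Random Gaussian readout mapping rates (Hz) to torques (N·m).

    The default entry s.d. is 0.05/sqrt(N), calibrated so that independent
    rate fluctuations of s.d. ~30 Hz across neurons produce torque
    fluctuations of s.d. ~1.5-2 N·m at N=200.  ``convention='literal'``
    uses 0.05/N instead.
    """
    if n_outputs >= n:
        raise ValueError("n_outputs must be smaller than n")
    if scale is None:
        scale = 0.05 / np.sqrt(n) if convention == "sqrt" else 0.05 / n
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_outputs, n)) * scale


def set_baseline(
    model: NetworkModel,
    mean_rate: float = 5.0,
    sd_rate: float = 5.0,
    seed: int = 0,
    n_moment_iters: int = 20,
) -> NetworkModel:
    """Attach a baseline input establishing resting rates of
    ``mean_rate`` ± ``sd_rate`` Hz.

    Target rest rates r* are drawn Gaussian, rectified at zero, and
    iteratively rescaled so the sample moments match the requested ones as
    closely as rectification allows.  The baseline is then
    ``h = (I - W) r*`` which makes ``x* = r*`` an exact fixed point of the
    dynamics under the rectified-linear nonlinearity (r* >= 0).
    """
    if mean_rate < 0 or sd_rate < 0:
        raise ValueError("mean and sd must be nonnegative")
    rng = np.random.default_rng(seed)
    r = mean_rate + sd_rate * rng.standard_normal(model.n)
    r = np.maximum(r, 0.0)
    for _ in range(n_moment_iters):
        sd = r.std()
        if sd == 0 or sd_rate == 0:
            r = np.full(model.n, mean_rate)
            break
        r = (r - r.mean()) * (sd_rate / sd) + mean_rate
        r = np.maximum(r, 0.0)
    h = (np.eye(model.n) - model.W) @ r
    return replace(model, h=h, rest_rate=r)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate(
    model: NetworkModel,
    u: np.ndarray,
    x0: np.ndarray,
    dt: float,
) -> dict[str, np.ndarray]:
    """Euler-integrate tau dx/dt = -x + W phi(x) + h + u.

    ``u`` has shape (K, N); the returned state trajectory has K+1 samples.
    Returns a dict with keys ``x``, ``r`` and, if the model has a readout,
    ``m`` (torques C r).  Raises :class:`SimulationDivergenceError` with the
    offending time index if the state becomes non-finite.
    """
    u = np.atleast_2d(np.asarray(u, dtype=float))
    if dt > model.tau / 10:
        raise ValueError("dt must be at most tau/10 for a faithful Euler step")
    K = u.shape[0]
    h = model.h if model.h is not None else np.zeros(model.n)
    x = np.empty((K + 1, model.n))
    x[0] = np.asarray(x0, dtype=float).reshape(model.n)
    c = dt / model.tau
    for k in range(K):
        xk = x[k]
        x[k + 1] = xk + c * (-xk + model.W @ model.phi(xk) + h + u[k])
        if not np.all(np.isfinite(x[k + 1])):
            raise SimulationDivergenceError(k + 1)
    r = model.phi(x)
    out = {"x": x, "r": r}
    if model.C is not None:
        out["m"] = model.torque(r)
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_network(path, model: NetworkModel) -> None:
    """Write a network to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=model.W)
        if model.C is not None:
            f.create_dataset("C", data=model.C)
        if model.h is not None:
            f.create_dataset("h", data=model.h)
        if model.rest_rate is not None:
            f.create_dataset("rest_rate", data=model.rest_rate)
        f.attrs["tau"] = model.tau
        f.attrs["nonlinearity"] = model.nonlinearity
        f.attrs["family"] = model.family
        if model.seed is not None:
            f.attrs["seed"] = model.seed


def load_network(path) -> NetworkModel:
    """Read a network written by :func:`save_network`."""
    import h5py

    with h5py.File(path, "r") as f:
        model = NetworkModel(
            W=f["W"][...],
            C=f["C"][...] if "C" in f else None,
            h=f["h"][...] if "h" in f else None,
            rest_rate=f["rest_rate"][...] if "rest_rate" in f else None,
            tau=float(f.attrs["tau"]),
            nonlinearity=str(f.attrs["nonlinearity"]),
            family=str(f.attrs["family"]),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )
    return model
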