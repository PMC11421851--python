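"""End-to-end analyses: delay sweeps, 2D motif dissection, Gramian
prediction sweeps, and reach sequences.

Each experiment builds its networks and tasks, runs the trajectory
optimizer, and returns an :class:`ExperimentResult` holding tidy metric
tables (pandas), the underlying optimal solutions, and the configuration
that produced them.  Runs are deterministic given (config, seed): seeds
enter only network/readout/baseline generation, never the solver.

Default task conditions (single reach): 8 radial targets of radius 12 cm
around a start point 30 cm in front of the shoulder, delay 300 ms,
movement window 900 ms, alpha_null = 1, alpha_effort = 5e-7, dt = 10 ms.
Toy task: delay 500 ms, movement window 2000 ms, y* = 20,
alpha_effort = 1e-5, dt = 1 ms.  Sequences: movement window 1400 ms, first
reach 300 ms, pause 600 ms (double) or 6 ms (compound), alpha_pause = 100,
alpha_null = 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__
from .arm import ArmParams, forward_kinematics, hand_jacobian, inverse_kinematics
from .costs import ControlTask
from .ilqr import ILQROptions, OptimalSolution, build_reach_problem, solve
from .metrics import (
    fit_prep_predictor,
    gramian_summary,
    preparation_index,
)
from .networks import (
    EnsembleSpec,
    NetworkModel,
    generate_2d,
    generate_ensemble,
    generate_isn,
    generate_readout,
    set_baseline,
)
from .subspaces import (
    EpochActivity,
    identify_subspaces,
    movement_onset,
    normalize_rates,
    occupancy,
)

__all__ = [
    "ExperimentResult",
    "HAND_CENTER",
    "radial_targets",
    "make_single_task",
    "make_toy_task",
    "make_sequence_task",
    "default_isn",
    "solve_reach",
    "hand_kinematics",
    "behavior_summary",
    "run_delay_sweep",
    "run_2d_analysis",
    "run_gramian_sweep",
    "run_sequence_experiment",
    "rates_tensor",
    "epoch_activity",
    "pca_movement_projection",
    "save_result",
]

HAND_CENTER = np.array([0.0, 0.30])  # default start point of the hand (m)


@dataclass
class ExperimentResult:
    """Metric tables plus the optimal solutions that produced them."""

    name: str
    config: dict
    tables: dict[str, pd.DataFrame]
    solutions: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)
    version: str = __version__


# ---------------------------------------------------------------------------
# Task and network builders
# ---------------------------------------------------------------------------


def radial_targets(
    n_targets: int = 8,
    radius: float = 0.12,
    center: np.ndarray = HAND_CENTER,
    params: ArmParams = ArmParams(),
    branch: str = "down",
) -> tuple[np.ndarray, np.ndarray]:
    """Joint-space start posture and the n radial reach targets.

    Targets sit on a circle of ``radius`` around ``center``; both the start
    point and the targets are converted to joint angles on the same
    inverse-kinematics branch.  Returns ``(theta0, theta_stars)`` with
    ``theta_stars`` of shape (n_targets, 2).
    """
    theta0 = inverse_kinematics(center, params, branch)
    phis = 2 * np.pi * np.arange(n_targets) / n_targets
    stars = np.stack(
        [
            inverse_kinematics(
                center + radius * np.array([np.cos(p), np.sin(p)]), params, branch
            )
            for p in phis
        ]
    )
    return theta0, stars


def make_single_task(
    theta0: np.ndarray,
    theta_star: np.ndarray,
    delay: float = 300.0,
    movement: float = 900.0,
    alpha_null: float = 1.0,
    alpha_effort: float = 5e-7,
) -> ControlTask:
    return ControlTask(
        delay=delay,
        movement=movement,
        theta0=theta0,
        theta_star=theta_star,
        alpha_null=alpha_null,
        alpha_effort=alpha_effort,
    )


def make_toy_task(
    delay: float = 500.0,
    movement: float = 2000.0,
    y_star: float = 20.0,
    alpha_null: float = 1.0,
    alpha_effort: float = 1e-5,
) -> ControlTask:
    return ControlTask(
        delay=delay,
        movement=movement,
        theta0=0.0,
        theta_star=y_star,
        alpha_null=alpha_null,
        alpha_effort=alpha_effort,
    )


def make_sequence_task(
    theta0: np.ndarray,
    theta_star1: np.ndarray,
    theta_star2: np.ndarray,
    delay: float = 500.0,
    movement: float = 1400.0,
    move1: float = 300.0,
    pause: float = 600.0,
    alpha_pause: float = 100.0,
    alpha_null: float = 10.0,
    alpha_effort: float = 5e-7,
) -> ControlTask:
    return ControlTask(
        delay=delay,
        movement=movement,
        theta0=theta0,
        theta_star=theta_star1,
        theta_star2=theta_star2,
        move1=move1,
        pause=pause,
        alpha_pause=alpha_pause,
        alpha_null=alpha_null,
        alpha_effort=alpha_effort,
    )


def default_isn(
    n: int = 200,
    seed: int = 0,
    exc_scale: float = 2.5,
    tau: float = 150.0,
    readout_seed: int | None = None,
    baseline_seed: int | None = None,
) -> NetworkModel:
    """Default ISN plant: stabilized network + random 2D readout + baseline."""
    model = generate_isn(n=n, seed=seed, exc_scale=exc_scale, tau=tau)
    model.C = generate_readout(n, 2, seed=seed if readout_seed is None else readout_seed)
    return set_baseline(
        model, seed=seed if baseline_seed is None else baseline_seed
    )


# ---------------------------------------------------------------------------
# Solving and behavioral summaries
# ---------------------------------------------------------------------------


def solve_reach(
    model: NetworkModel,
    effector,
    task: ControlTask,
    dt: float,
    options: ILQROptions = ILQROptions(),
) -> tuple[OptimalSolution, object]:
    """Build and solve one reach problem; returns (solution, problem)."""
    problem = build_reach_problem(model, effector, task, dt)
    return solve(problem, options=options), problem


def hand_kinematics(
    Z: np.ndarray, n_neurons: int, params: ArmParams = ArmParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Hand position (K+1, 2) and speed (K+1,) from an augmented trajectory."""
    theta = Z[:, n_neurons : n_neurons + 2]
    omega = Z[:, n_neurons + 2 : n_neurons + 4]
    pos = np.stack([forward_kinematics(t, params)[0] for t in theta])
    speed = np.array(
        [np.linalg.norm(hand_jacobian(t, params) @ w) for t, w in zip(theta, omega)]
    )
    return pos, speed


def behavior_summary(
    sol: OptimalSolution,
    task: ControlTask,
    n_neurons: int,
    dt: float,
    params: ArmParams = ArmParams(),
    settle_radius: float = 0.005,
) -> dict:
    """Post-hoc behavioral checks: delay stillness, reach duration, holding.

    ``reach_duration`` is the time from the go cue after which the hand
    stays within ``settle_radius`` (m) of the target for the rest of the
    trial; ``hold_time`` is the remaining time spent there.
    """
    t = task.times(dt)
    pos, speed = hand_kinematics(sol.Z, n_neurons, params)
    start, _ = forward_kinematics(np.asarray(task.theta0).reshape(2), params)
    target, _ = forward_kinematics(np.asarray(task.theta_star).reshape(2), params)
    delay_mask = t < -1e-9
    max_drift = (
        float(np.linalg.norm(pos[delay_mask] - start, axis=1).max())
        if delay_mask.any()
        else 0.0
    )
    dist = np.linalg.norm(pos - target, axis=1)
    mov = t >= -1e-9
    inside = dist[mov] < settle_radius
    # earliest index after which the hand never leaves the settle radius
    settled_from = None
    bad = np.nonzero(~inside)[0]
    last_bad = bad[-1] if bad.size else -1
    if last_bad + 1 < inside.size:
        settled_from = t[mov][last_bad + 1]
    return {
        "delay_drift_m": max_drift,
        "reach_duration_ms": settled_from,
        "hold_time_ms": (task.movement - settled_from) if settled_from is not None else 0.0,
        "peak_speed_m_s": float(speed.max()),
        "final_dist_m": float(dist[-1]),
    }


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------


def run_delay_sweep(
    model: NetworkModel,
    delays: Iterable[float] = (0.0, 100.0, 200.0, 300.0, 500.0, 800.0),
    n_targets: int = 8,
    radius: float = 0.12,
    movement: float = 900.0,
    dt: float = 10.0,
    arm: ArmParams = ArmParams(),
    options: ILQROptions = ILQROptions(),
    keep_solutions: bool = True,
) -> ExperimentResult:
    """Optimal single reaches across preparation durations.

    Produces per-(delay, target) cost breakdowns and preparation indices,
    plus a per-delay summary with costs normalized by the mean total cost
    at zero delay.
    """
    theta0, stars = radial_targets(n_targets, radius, params=arm)
    rows = []
    solutions = {}
    failures = []
    for delay in delays:
        for j, star in enumerate(stars):
            task = make_single_task(theta0, star, delay=delay, movement=movement)
            try:
                sol, problem = solve_reach(model, arm, task, dt, options)
            except Exception as e:  # solver failures recorded, run continues
                failures.append({"delay": delay, "target": j, "error": str(e)})
                continue
            idx = (
                preparation_index(sol.U, delay=delay, dt=dt) if delay > 0 else 0.0
            )
            b = sol.breakdown
            rows.append(
                {
                    "delay": delay,
                    "target": j,
                    "prep_index": idx,
                    "J_total": b.total,
                    "J_target": b.target,
                    "J_null": b.null,
                    "J_effort": b.effort,
                    "converged": sol.converged,
                    "stalled": sol.stalled,
                }
            )
            if keep_solutions:
                solutions[(delay, j)] = sol
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("delay")[["prep_index", "J_total", "J_target", "J_null", "J_effort"]]
        .mean()
        .reset_index()
    )
    if (summary["delay"] == 0.0).any():
        j0 = float(summary.loc[summary["delay"] == 0.0, "J_total"].iloc[0])
        for col in ("J_total", "J_target", "J_null", "J_effort"):
            summary[col + "_norm"] = summary[col] / j0
    config = {
        "delays": list(delays),
        "n_targets": n_targets,
        "radius": radius,
        "movement": movement,
        "dt": dt,
        "n": model.n,
        "seed": model.seed,
    }
    return ExperimentResult(
        "delay-sweep",
        config,
        {"reaches": table, "summary": summary},
        solutions,
        failures=failures,
    )


def run_2d_analysis(
    kinds: Iterable[str] = ("feedforward", "oscillatory"),
    w_grid: Iterable[float] = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0),
    readout_angles: Iterable[float] = (0.0, np.pi / 2),
    delay: float = 500.0,
    movement: float = 2000.0,
    dt: float = 1.0,
    options: ILQROptions = ILQROptions(),
    keep_solutions: bool = False,
) -> ExperimentResult:
    """Dissect preparation in the two-unit motifs across connectivity
    strengths and readout orientations.

    Readout angle 0 reads unit 0 (the feedforward *source*); pi/2 reads
    unit 1 (the *sink*).  Reports the preparation index, total cost, and
    total preparatory input energy per configuration.
    """
    rows = []
    solutions = {}
    for kind in kinds:
        for w in w_grid:
            for ang in readout_angles:
                model = generate_2d(kind, w)
                model.C = np.array([[np.cos(ang), np.sin(ang)]])
                task = make_toy_task(delay=delay, movement=movement)
                sol, problem = solve_reach(model, "integrator", task, dt, options)
                idx = preparation_index(sol.U, delay=delay, dt=dt)
                t = task.times(dt)[:-1]
                prep_energy = float(np.sum(sol.U[t < -1e-9] ** 2) * dt)
                rows.append(
                    {
                        "kind": kind,
                        "w": w,
                        "readout_angle": ang,
                        "prep_index": idx,
                        "J_total": sol.cost,
                        "prep_input_energy": prep_energy,
                        "converged": sol.converged,
                    }
                )
                if keep_solutions:
                    solutions[(kind, w, ang)] = sol
    config = {
        "kinds": list(kinds),
        "w_grid": list(w_grid),
        "readout_angles": list(readout_angles),
        "delay": delay,
        "movement": movement,
        "dt": dt,
    }
    return ExperimentResult(
        "twod", config, {"motifs": pd.DataFrame(rows)}, solutions
    )


def _prep_index_of_network(
    model: NetworkModel,
    targets: np.ndarray,
    theta0: np.ndarray,
    delay: float,
    movement: float,
    dt: float,
    options: ILQROptions,
    arm: ArmParams,
) -> float:
    vals = []
    for star in targets:
        task = make_single_task(theta0, star, delay=delay, movement=movement)
        sol, _ = solve_reach(model, arm, task, dt, options)
        vals.append(preparation_index(sol.U, delay=delay, dt=dt))
    return float(np.mean(vals))


def run_gramian_sweep(
    n: int = 48,
    exc_scales: Iterable[float] = (1.5, 2.5, 3.5),
    taus: Iterable[float] = (100.0, 150.0, 200.0),
    seeds: Iterable[int] = (0, 1, 2),
    targets_per_net: int = 2,
    delay: float = 300.0,
    movement: float = 900.0,
    dt: float = 10.0,
    radius: float = 0.12,
    transfer_specs: Iterable[EnsembleSpec] | None = None,
    transfer_taus: Iterable[float] | None = None,
    options: ILQROptions = ILQROptions(),
    folds: int = 5,
) -> ExperimentResult:
    """Predict the preparation index from nullspace observability (alpha)
    and readout controllability (beta).

    ISNs varied in excitatory strength and time constant are solved on the
    reach task; their preparation indices are regressed on (alpha, beta)
    with cross-validation.  If transfer families are given, the ISN-trained
    predictor is evaluated on them without refitting.
    """
    arm = ArmParams()
    theta0, stars = radial_targets(8, radius, params=arm)
    targets = stars[:: max(1, 8 // targets_per_net)][:targets_per_net]
    rows = []
    failures = []

    def _record(model: NetworkModel, family: str, scale, tau) -> None:
        try:
            gs = gramian_summary(model)
            idx = _prep_index_of_network(
                model, targets, theta0, delay, movement, dt, options, arm
            )
        except Exception as e:
            failures.append({"family": family, "scale": scale, "tau": tau, "error": str(e)})
            return
        rows.append(
            {
                "family": family,
                "scale": scale,
                "tau": tau,
                "seed": model.seed,
                "alpha": gs.alpha,
                "beta": gs.beta,
                "prep_index": idx,
            }
        )

    for scale in exc_scales:
        for tau in taus:
            for seed in seeds:
                try:
                    model = generate_isn(n=n, seed=seed, exc_scale=scale, tau=tau)
                except Exception as e:  # unstabilizable draws are skipped
                    failures.append(
                        {"family": "isn", "scale": scale, "tau": tau,
                         "seed": seed, "error": str(e)}
                    )
                    continue
                model.C = generate_readout(n, 2, seed=seed)
                model = set_baseline(model, seed=seed)
                _record(model, "isn", scale, tau)

    records = pd.DataFrame([r for r in rows if r["family"] == "isn"])
    prediction = fit_prep_predictor(records, folds=folds)

    transfer_table = None
    transfer_r2 = None
    if transfer_specs is not None:
        t_taus = list(transfer_taus) if transfer_taus is not None else [150.0]
        for spec in transfer_specs:
            for tau in t_taus:
                model = generate_ensemble(spec, tau=tau)
                model.C = generate_readout(spec.n, 2, seed=spec.seed)
                model = set_baseline(model, seed=spec.seed)
                _record(model, spec.family, spec.scale, tau)
        transfer_table = pd.DataFrame([r for r in rows if r["family"] != "isn"])
        if len(transfer_table):
            Xz = (
                transfer_table[["alpha", "beta"]].to_numpy()
                - prediction.zscore_mean
            ) / prediction.zscore_std
            y = transfer_table["prep_index"].to_numpy()
            pred = (
                prediction.intercept
                + Xz[:, 0] * prediction.k_alpha
                + Xz[:, 1] * prediction.k_beta
            )
            transfer_r2 = 1.0 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)

    tables = {"records": pd.DataFrame(rows)}
    config = {
        "n": n,
        "exc_scales": list(exc_scales),
        "taus": list(taus),
        "seeds": list(seeds),
        "targets_per_net": targets_per_net,
        "delay": delay,
        "movement": movement,
        "dt": dt,
    }
    extras = {"prediction": prediction, "transfer_r2": transfer_r2}
    if transfer_table is not None:
        tables["transfer"] = transfer_table
    return ExperimentResult(
        "gramian-sweep", config, tables, extras=extras, failures=failures
    )


# ---------------------------------------------------------------------------
# Activity tensors and subspace pipeline
# ---------------------------------------------------------------------------


def rates_tensor(model: NetworkModel, solutions: Iterable[OptimalSolution]) -> np.ndarray:
    """Stack firing rates of several conditions into an (N, M, T) tensor."""
    rs = [model.phi(sol.Z[:, : model.n]).T for sol in solutions]
    return np.stack(rs, axis=1)


def epoch_activity(
    rates_norm: np.ndarray,
    times: np.ndarray,
    prep_window: tuple[float, float] = (-300.0, 0.0),
    mov_window: tuple[float, float] = (50.0, 350.0),
) -> EpochActivity:
    """Slice normalized rates into the preparatory and movement epochs.

    Windows are in ms relative to the go cue; the preparatory default is
    the 300 ms before delay end, the movement default the 300 ms window
    starting 50 ms after the go cue.
    """
    N = rates_norm.shape[0]
    pm = (times >= prep_window[0] - 1e-9) & (times < prep_window[1] - 1e-9)
    mm = (times >= mov_window[0] - 1e-9) & (times < mov_window[1] - 1e-9)
    return EpochActivity(
        prep=rates_norm[:, :, pm].reshape(N, -1),
        mov=rates_norm[:, :, mm].reshape(N, -1),
    )


def run_sequence_experiment(
    model: NetworkModel,
    pairs: Iterable[tuple[int, int]] | None = None,
    n_targets: int = 8,
    radius: float = 0.12,
    single_delay: float = 300.0,
    single_movement: float = 900.0,
    seq_delay: float = 500.0,
    seq_movement: float = 1400.0,
    move1: float = 300.0,
    dt: float = 10.0,
    arm: ArmParams = ArmParams(),
    options: ILQROptions = ILQROptions(),
    d_prep: int = 6,
    d_mov: int = 6,
    subspace_seed: int = 0,
    single_solutions: list[OptimalSolution] | None = None,
) -> ExperimentResult:
    """Single, double (600 ms pause) and compound (6 ms pause) reaches, with
    preparatory/movement-subspace identification and occupancy curves.

    Subspaces are fitted on single reaches plus the first reaches of the
    double sequences only; second-reach and compound activity is excluded
    from the fit.  Occupancy curves are reported for all three condition
    sets, along with hand-speed-based movement onsets.
    """
    theta0, stars = radial_targets(n_targets, radius, params=arm)
    if pairs is None:
        pairs = [(i, (i + 3) % n_targets) for i in range(n_targets)]
    pairs = list(pairs)

    if single_solutions is None:
        single_solutions = []
        for star in stars:
            task = make_single_task(
                theta0, star, delay=single_delay, movement=single_movement
            )
            sol, _ = solve_reach(model, arm, task, dt, options)
            single_solutions.append(sol)
    single_task = make_single_task(
        theta0, stars[0], delay=single_delay, movement=single_movement
    )

    seq_solutions: dict[str, list[OptimalSolution]] = {"double": [], "compound": []}
    for variant, pause in (("double", 600.0), ("compound", 6.0)):
        for i, j in pairs:
            task = make_sequence_task(
                theta0,
                stars[i],
                stars[j],
                delay=seq_delay,
                movement=seq_movement,
                move1=move1,
                pause=pause,
            )
            sol, _ = solve_reach(model, arm, task, dt, options)
            seq_solutions[variant].append(sol)
    seq_task = {
        "double": make_sequence_task(
            theta0, stars[0], stars[0], delay=seq_delay, movement=seq_movement,
            move1=move1, pause=600.0,
        ),
        "compound": make_sequence_task(
            theta0, stars[0], stars[0], delay=seq_delay, movement=seq_movement,
            move1=move1, pause=6.0,
        ),
    }

    # --- subspace identification: singles + first reaches of doubles ---
    t_single = single_task.times(dt)
    t_seq = seq_task["double"].times(dt)
    rates_single = normalize_rates(rates_tensor(model, single_solutions))
    rates_double = normalize_rates(rates_tensor(model, seq_solutions["double"]))
    ep_s = epoch_activity(rates_single, t_single)
    ep_d = epoch_activity(rates_double, t_seq)  # first-reach windows only
    epochs = EpochActivity(
        prep=np.concatenate([ep_s.prep, ep_d.prep], axis=1),
        mov=np.concatenate([ep_s.mov, ep_d.mov], axis=1),
    )
    pair_basis = identify_subspaces(epochs, d_prep, d_mov, seed=subspace_seed)

    # --- occupancy curves and movement onsets ---
    occ_tables = {}
    onsets = {}
    for name, sols, times in (
        ("single", single_solutions, t_single),
        ("double", seq_solutions["double"], t_seq),
        ("compound", seq_solutions["compound"], t_seq),
    ):
        rn = normalize_rates(rates_tensor(model, sols))
        occ_tables[name] = pd.DataFrame(
            {
                "time": times,
                "occ_prep": occupancy(rn, pair_basis.W_prep, normalize=True),
                "occ_mov": occupancy(rn, pair_basis.W_mov, normalize=True),
            }
        )
        speeds = [hand_kinematics(s.Z, model.n, arm)[1] for s in sols]
        onsets[name] = [
            movement_onset(sp, dt, t0=times[0]) for sp in speeds
        ]

    config = {
        "n_targets": n_targets,
        "pairs": pairs,
        "radius": radius,
        "single_delay": single_delay,
        "seq_delay": seq_delay,
        "seq_movement": seq_movement,
        "move1": move1,
        "dt": dt,
        "d_prep": d_prep,
        "d_mov": d_mov,
    }
    tables = {f"occupancy_{k}": v for k, v in occ_tables.items()}
    return ExperimentResult(
        "sequence",
        config,
        tables,
        solutions={"single": single_solutions, **seq_solutions},
        extras={"subspaces": pair_basis, "onsets": onsets, "times": {"single": t_single, "seq": t_seq}},
    )


def pca_movement_projection(
    model: NetworkModel,
    solutions_by_delay: dict[float, OptimalSolution],
    movement: float = 900.0,
    dt: float = 10.0,
    n_components: int = 2,
) -> dict[float, np.ndarray]:
    """Project movement-epoch firing rates into PCs shared across delays.

    The PCA basis is fitted on the pooled movement-epoch activity of all
    delays, so trajectories for different preparation durations live in a
    common low-dimensional space and can be compared directly.
    """
    from sklearn.decomposition import PCA

    n_mov = int(round(movement / dt))
    segments = {}
    for delay, sol in solutions_by_delay.items():
        k0 = int(round(delay / dt))
        segments[delay] = model.phi(sol.Z[k0 : k0 + n_mov + 1, : model.n])
    pooled = np.concatenate(list(segments.values()), axis=0)
    pca = PCA(n_components=n_components).fit(pooled)
    return {d: pca.transform(seg) for d, seg in segments.items()}


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def save_result(result: ExperimentResult, outdir) -> None:
    """Write an experiment's tables (CSV), solutions (HDF5) and config (YAML)."""
    import os

    import h5py
    import yaml

    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "config.yaml"), "w") as f:
        yaml.safe_dump(
            {"experiment": result.name, "version": result.version, **result.config}, f
        )
    for name, table in result.tables.items():
        table.to_csv(os.path.join(outdir, f"{name}.csv"), index=False)
    if result.solutions:
        with h5py.File(os.path.join(outdir, "solutions.h5"), "w") as f:
            for key, sol in result.solutions.items():
                sols = sol if isinstance(sol, list) else [sol]
                for i, s in enumerate(sols):
                    g = f.create_group(f"{key}/{i}" if isinstance(sol, list) else str(key))
                    g.create_dataset("U", data=s.U)
                    g.create_dataset("Z", data=s.Z)
                    g.attrs["cost"] = s.cost
                    g.attrs["converged"] = s.converged
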