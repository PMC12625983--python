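"""Evaluation protocols: robustness, continual learning, engagement statistics.

These are the standard experiments around the drift model:

* *robustness*: how much does the readout err when the learned weights are
  hit by i.i.d. Gaussian perturbations?  Drift discovers sparsely engaged
  solutions whose disengaged neurons absorb current perturbations, so the
  post-drift error is lower; the gain grows with the weight-norm bound.
* *continual learning*: memories are added one at a time (allocate, then
  gradient descent in U on the new memory only).  Interleaved drift does not
  change the current perturbations new learning inflicts on stored memories,
  but sparsely engaged stored representations translate those perturbations
  into smaller representation and readout changes.
* *engagement statistics*: fractions of engaged / inactive / saturated
  (neuron, condition) pairs along a drift trajectory, plus per-condition
  engaged-set rasters.
* the two-neuron worked example: a fully deterministic pipeline
  (allocate → η-learn → drift → allocate → η-learn) whose numbers can be
  followed by hand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import child_seed, substream
from .drift import DriftConfig, DriftTrajectory, run_drift
from .eta import EtaState, build_extended_basis, from_eta, to_eta
from .learning import LearnConfig, allocate, learn_gd_U, learn_gd_eta
from .network import (
    NetworkConfig,
    TaskSpec,
    WeightState,
    forward,
    generate_task,
    partition_neurons,
    phi,
)

__all__ = [
    "RobustnessSample",
    "RobustnessReport",
    "ContinualReport",
    "learn_solution",
    "robustness_eval",
    "robustness_sweep",
    "continual_experiment",
    "continual_comparison",
    "engagement_stats",
    "toy_fig4",
    "toy_task",
]

logger = logging.getLogger(__name__)


@dataclass
class RobustnessSample:
    """One robustness evaluation: signed readout errors under U perturbations."""

    rms: float
    errors: np.ndarray  # (n, Nz, P) signed errors
    perturb_sd: float
    n_samples: int


@dataclass
class RobustnessReport:
    """Paired before/after-drift robustness at one weight-norm bound."""

    Umax: float
    rms_before: np.ndarray  # per seed
    rms_after: np.ndarray
    perturb_sd: float
    n_samples: int

    @property
    def scaled_improvement(self) -> np.ndarray:
        return (self.rms_before - self.rms_after) / self.rms_before

    @property
    def mean_scaled_improvement(self) -> float:
        return float(np.mean(self.scaled_improvement))


@dataclass
class ContinualReport:
    """Per-(stored μ, new ν) interference records for one arm."""

    arm: str  # "with_drift" or "without_drift"
    records: pd.DataFrame  # seed, mu, nu, current_rms, repr_change, readout_rms
    current_perturbations: np.ndarray  # pooled Δη entries across (mu, nu, seed)


def learn_solution(
    task: TaskSpec,
    cfg: NetworkConfig,
    learn_cfg: LearnConfig | None = None,
    rng: np.random.Generator | None = None,
    *,
    init_sd: float = 0.1,
) -> EtaState:
    """Reach the solution space: init U ~ N(0, 0.1), allocate all η columns
    near α/2, then batch gradient descent in U over all P conditions."""
    lc = learn_cfg or LearnConfig(optimizer="adaptive_gd")
    rng = rng or np.random.default_rng(task.seed)
    frame = build_extended_basis(task.X)
    U0 = rng.normal(0.0, init_sd, size=(cfg.Ny, cfg.Nx))
    state = to_eta(U0, frame)
    for mu in range(cfg.P):
        state = allocate(state, mu, lc, rng, alpha=cfg.alpha)
    ws = WeightState(U=from_eta(state), b=state.bias.copy())
    ws, rep = learn_gd_U(ws, task, list(range(cfg.P)), lc, alpha=cfg.alpha)
    if not rep.converged:
        logger.warning("learning did not reach tolerance (rms=%.3g)", rep.final_rms)
    return to_eta(ws.U, frame, learned=frozenset(range(cfg.P)), bias=ws.b)


def robustness_eval(
    state: WeightState,
    task: TaskSpec,
    rho: float,
    n: int,
    rng: np.random.Generator,
    *,
    alpha: float = 5.0,
) -> RobustnessSample:
    """Signed readout errors under n i.i.d. N(0, ρ) weight perturbations.

    Perturbed weights are evaluated as-is (no norm-bound clipping).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    errors = np.empty((n,) + task.Z.shape)
    for s in range(n):
        dU = rng.normal(0.0, rho, size=state.U.shape) if rho > 0 else 0.0
        Zp = task.W @ phi((state.U + dU) @ task.X + state.b[:, None], alpha)
        errors[s] = Zp - task.Z
    return RobustnessSample(
        rms=float(np.sqrt(np.mean(errors**2))), errors=errors, perturb_sd=rho, n_samples=n
    )


def robustness_sweep(
    umax_grid: list[float],
    cfg: NetworkConfig | None = None,
    *,
    n_seeds: int = 10,
    seed: int = 0,
    rho: float = 1.0,
    n_perturb: int = 100,
    drift_steps: int = 10_000,
    sigma: float = 0.05,
    learn_cfg: LearnConfig | None = None,
) -> list[RobustnessReport]:
    """Learn, evaluate, drift under each Umax, re-evaluate (paired seeds).

    The same tasks, learned states, and perturbation draws are reused across
    the Umax grid, so differences along the grid isolate the effect of the
    bound on the solutions drift can reach.
    """
    if not umax_grid:
        raise ValueError("umax_grid must be nonempty")
    cfg = cfg or NetworkConfig()
    states, tasks, pre = [], [], []
    for k in range(n_seeds):
        task = generate_task(cfg, child_seed(seed, f"task-{k}"))
        st = learn_solution(task, cfg, learn_cfg, substream(seed, f"learn-{k}"))
        ws = WeightState(U=from_eta(st), b=st.bias.copy())
        pre_k = robustness_eval(
            ws, task, rho, n_perturb, substream(seed, f"perturb-{k}"), alpha=cfg.alpha
        )
        tasks.append(task)
        states.append(st)
        pre.append(pre_k.rms)
    reports = []
    for Umax in umax_grid:
        rms_after = np.empty(n_seeds)
        for k in range(n_seeds):
            dc = DriftConfig(
                sigma=sigma,
                Umax=Umax,
                n_steps=drift_steps,
                record_every=max(drift_steps, 1),
                seed=child_seed(seed, f"drift-{k}"),
            )
            traj = run_drift(states[k], tasks[k], dc, alpha=cfg.alpha)
            ws = WeightState(
                U=traj.eta_snapshots[-1] @ states[k].frame.Xinv, b=states[k].bias.copy()
            )
            post = robustness_eval(
                ws,
                tasks[k],
                rho,
                n_perturb,
                substream(seed, f"perturb-{k}"),
                alpha=cfg.alpha,
            )
            rms_after[k] = post.rms
        reports.append(
            RobustnessReport(
                Umax=float(Umax),
                rms_before=np.asarray(pre),
                rms_after=rms_after,
                perturb_sd=rho,
                n_samples=n_perturb,
            )
        )
        logger.info(
            "Umax=%g: mean scaled improvement %.3f", Umax, reports[-1].mean_scaled_improvement
        )
    return reports


def continual_experiment(
    cfg: NetworkConfig,
    with_drift: bool,
    drift_steps: int,
    seed: int,
    *,
    init_sd: float = 15.0,
    Umax: float = 350.0,
    sigma: float = 0.05,
    learn_cfg: LearnConfig | None = None,
) -> ContinualReport:
    """One seed of the continual-learning protocol (one arm).

    Sequentially for ν = 1..P: allocate η_ν, learn ν by gradient descent in U
    on the new memory only, then (with_drift) drift constrained to memories
    1..ν.  After each addition, the change that learning ν inflicted on every
    stored memory μ < ν is recorded: the η-column (input current)
    perturbation, the representation change ‖ΔY_μ‖, and the stored readout
    RMS error.  Both arms consume identical task / init / allocation
    randomness so they differ only by the interleaved drift.
    """
    lc = learn_cfg or LearnConfig(optimizer="adaptive_gd")
    task = generate_task(cfg, child_seed(seed, "task"))
    frame = build_extended_basis(task.X)
    U0 = init_sd * substream(seed, "init").standard_normal((cfg.Ny, cfg.Nx))
    state = to_eta(U0, frame)
    alloc_rng = substream(seed, "alloc")
    rows = []
    pooled: list[np.ndarray] = []
    for nu in range(cfg.P):
        state = allocate(state, nu, lc, alloc_rng, alpha=cfg.alpha)
        eta_before = state.eta.copy()
        ws = WeightState(U=from_eta(state), b=state.bias.copy())
        ws, _ = learn_gd_U(ws, task, [nu], lc, alpha=cfg.alpha)
        state = to_eta(ws.U, frame, learned=state.learned | {nu}, bias=ws.b)
        for mu in range(nu):
            d_eta = state.eta[:, mu] - eta_before[:, mu]
            y_before = phi(eta_before[:, mu] + state.bias, cfg.alpha)
            y_after = phi(state.eta[:, mu] + state.bias, cfg.alpha)
            err = task.W @ y_after - task.Z[:, mu]
            rows.append(
                {
                    "seed": seed,
                    "mu": mu,
                    "nu": nu,
                    "current_rms": float(np.sqrt(np.mean(d_eta**2))),
                    "repr_change": float(np.linalg.norm(y_after - y_before)),
                    "readout_rms": float(np.sqrt(np.mean(err**2))),
                }
            )
            pooled.append(d_eta)
        if with_drift and nu < cfg.P - 1:
            dc = DriftConfig(
                sigma=sigma,
                Umax=Umax,
                n_steps=drift_steps,
                record_every=max(drift_steps, 1),
                constrained=frozenset(range(nu + 1)),
                seed=child_seed(seed, f"drift-{nu}"),
            )
            traj = run_drift(state, task, dc, alpha=cfg.alpha)
            state = EtaState(
                eta=traj.eta_snapshots[-1],
                frame=frame,
                learned=state.learned,
                bias=state.bias.copy(),
            )
    return ContinualReport(
        arm="with_drift" if with_drift else "without_drift",
        records=pd.DataFrame(rows),
        current_perturbations=np.concatenate(pooled) if pooled else np.empty(0),
    )


def continual_comparison(
    cfg: NetworkConfig | None = None,
    *,
    n_seeds: int = 10,
    drift_steps: int = 10_000,
    seed: int = 0,
    **kwargs,
) -> tuple[ContinualReport, ContinualReport]:
    """Paired with-drift / without-drift arms over ``n_seeds`` shared seeds."""
    cfg = cfg or NetworkConfig()
    arms = []
    for with_drift in (True, False):
        reps = [
            continual_experiment(
                cfg, with_drift, drift_steps, child_seed(seed, f"rep-{k}"), **kwargs
            )
            for k in range(n_seeds)
        ]
        arms.append(
            ContinualReport(
                arm=reps[0].arm,
                records=pd.concat([r.records for r in reps], ignore_index=True),
                current_perturbations=np.concatenate(
                    [r.current_perturbations for r in reps]
                ),
            )
        )
    return arms[0], arms[1]


def engagement_stats(
    trajectory: DriftTrajectory, *, alpha: float = 5.0, bias: np.ndarray | None = None
) -> tuple[pd.DataFrame, dict[int, np.ndarray]]:
    """Pooled engagement fractions over time plus per-condition engaged rasters.

    Rasters are (T × Ny) booleans recomputed from the recorded η snapshots
    with the strict-engagement convention (0 < current < α).
    """
    if trajectory.times.size == 0:
        raise ValueError("trajectory is empty")
    df = trajectory.fractions_frame()
    b = np.zeros(trajectory.eta_snapshots.shape[1]) if bias is None else np.asarray(bias)
    rasters: dict[int, np.ndarray] = {}
    for mu in trajectory.constrained:
        cur = trajectory.eta_snapshots[:, :, mu] + b[None, :]
        rasters[mu] = (cur > 0.0) & (cur < alpha)
    return df, rasters


def toy_task() -> tuple[NetworkConfig, TaskSpec]:
    """The two-neuron worked example: (1,−1) → 4 and (−0.5,1) → 2, w = (1,1)."""
    cfg = NetworkConfig(Nx=2, Ny=2, Nz=1, P=2, alpha=5.0)
    X = np.array([[1.0, -0.5], [-1.0, 1.0]])
    W = np.array([[1.0, 1.0]])
    Z = np.array([[4.0, 2.0]])
    return cfg, TaskSpec(X=X, W=W, Z=Z)


def toy_fig4(
    cfg: LearnConfig | None = None,
    *,
    drift_steps: int = 300,
    sigma: float = 0.2,
    seed: int = 0,
) -> dict:
    """Run the worked example end to end and return a structured transcript.

    Stages: allocate η column 1 to (4,4) → plain gradient descent in η to the
    solution space at (2,2) → drift constrained to mapping 1 → allocate η
    column 2 at the engaged center (2.5, 2.5) → gradient descent in η on
    column 2 only.  The transcript carries every intermediate η state, the
    learning reports, and the final readouts (4, 2).
    """
    lc = cfg or LearnConfig(lr=0.01, max_steps=100_000, tol=1e-5)
    net, task = toy_task()
    frame = build_extended_basis(task.X)
    state = EtaState(eta=np.zeros((2, 2)), frame=frame)
    t: dict = {"eta_initial": state.eta.copy()}

    state.eta[:, 0] = 4.0  # allocation point printed for the first mapping
    t["eta_after_alloc1"] = state.eta.copy()
    state, rep1 = learn_gd_eta(state, task, 0, lc, alpha=net.alpha)
    t["eta_after_learn1"] = state.eta.copy()
    t["learn1"] = rep1

    dc = DriftConfig(
        sigma=sigma, n_steps=drift_steps, record_every=max(drift_steps // 10, 1), seed=seed
    )
    traj = run_drift(state, task, dc, alpha=net.alpha)
    state = EtaState(
        eta=traj.eta_snapshots[-1], frame=frame, learned=state.learned, bias=state.bias
    )
    t["eta_after_drift"] = state.eta.copy()
    t["drift_conservation"] = float(traj.conservation.max())

    state.eta[:, 1] = net.alpha / 2.0  # allocation at the engaged-regime center
    t["eta_after_alloc2"] = state.eta.copy()
    col0_before = state.eta[:, 0].copy()
    state, rep2 = learn_gd_eta(state, task, 1, lc, alpha=net.alpha)
    t["eta_after_learn2"] = state.eta.copy()
    t["learn2"] = rep2
    t["col1_max_change_during_learn2"] = float(
        np.max(np.abs(state.eta[:, 0] - col0_before))
    )

    ws = WeightState(U=from_eta(state), b=state.bias.copy())
    snap = forward(ws, task, net)
    t["final_readouts"] = snap.Zhat.ravel().copy()
    t["final_partition"] = partition_neurons(snap, net).labels.copy()
    t["task"] = task
    return t
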