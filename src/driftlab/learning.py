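"""Allocation and gradient-descent learning, in weight and in η-coordinates.

Learning minimizes the squared readout error J² = Σ_μ ‖W·Φ(U·x_μ + b) − z_μ‖²
over a set of target conditions, holding the readout W and bias fixed.  Two
parameterizations are available:

* weight coordinates: ΔU = −λ·∇_U J², the hand-coded gradient
  2·(Wᵀ(ẑ−z) ⊙ Φ′(C))·Xᵀ restricted to target conditions;
* η-coordinates: for a single condition μ the error depends only on column μ
  of η, so Δη_{i,μ} = −λ·2J_μ·(Wᵀ)_i·Φ′(η_{i,μ}+b_i) and every other column
  is untouched — sequential memories can be added without interference.

Because disengaged neurons have Φ′ = 0, a condition whose neurons are all
inactive or saturated yields an exactly zero gradient and cannot be learned
from that state.  *Allocation* escapes this local optimum by resampling the
new condition's η column near the center of the engaged regime,
η_μ ~ N(α/2, 0.1), which makes (with overwhelming probability) every neuron
engaged and gradient-bearing without touching any stored memory.

Plain gradient descent is the default; an Adam-style adaptive optimizer is
available and is the practical choice at simulation scale, where readout
weights ~N(0,10) make the plain-GD stable step size impractically small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import child_seed, substream
from .drift import DriftConfig, run_drift
from .eta import EtaFrame, EtaState, build_extended_basis, from_eta, to_eta
from .network import NetworkConfig, TaskSpec, WeightState, generate_task, phi, phi_derivative

__all__ = [
    "LearnConfig",
    "LearnReport",
    "LearnabilityReport",
    "allocate",
    "learn_gd_U",
    "learn_gd_eta",
    "learnability_protocol",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LearnConfig:
    """Gradient-descent settings.

    ``tol`` is an absolute RMS readout-error tolerance; when None it is set
    to ``rtol`` times the RMS of the target readouts (a mapping counts as
    successfully learned when the stored-memory RMS error is below this).
    """

    lr: float = 0.001
    max_steps: int = 20_000
    tol: float | None = None
    rtol: float = 1e-3
    optimizer: str = "plain_gd"  # or "adaptive_gd"
    alloc_mean: float | None = None  # None -> alpha / 2
    alloc_sd: float = 0.1

    def __post_init__(self) -> None:
        if not self.lr > 0:
            raise ValueError("lr must be positive")
        if self.tol is not None and not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.optimizer not in ("plain_gd", "adaptive_gd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class LearnReport:
    converged: bool
    final_loss: float
    final_rms: float
    steps_used: int
    tol: float
    per_mapping_success: dict[int, bool] = field(default_factory=dict)


@dataclass
class LearnabilityReport:
    """Learned-mapping counts across an initialization grid."""

    init_sd_grid: np.ndarray
    counts: np.ndarray  # (n_grid, n_seeds)
    use_allocation: bool

    @property
    def mean_counts(self) -> np.ndarray:
        return self.counts.mean(axis=1)

    @property
    def se_counts(self) -> np.ndarray:
        n = self.counts.shape[1]
        return self.counts.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(len(self.init_sd_grid))


def _resolve_tol(cfg: LearnConfig, Z_targets: np.ndarray) -> float:
    if cfg.tol is not None:
        return cfg.tol
    rms_z = float(np.sqrt(np.mean(Z_targets**2)))
    return cfg.rtol * max(rms_z, 1.0)


class _Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = self.v = None
        self.t = 0

    def update(self, grad: np.ndarray) -> np.ndarray:
        if self.m is None:
            self.m = np.zeros_like(grad)
            self.v = np.zeros_like(grad)
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = self.b2 * self.v + (1 - self.b2) * grad**2
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        return -self.lr * mhat / (np.sqrt(vhat) + self.eps)


def allocate(
    state: EtaState,
    mu: int,
    cfg: LearnConfig,
    rng: np.random.Generator,
    *,
    alpha: float = 5.0,
) -> EtaState:
    """Resample η column μ near the center of the engaged regime.

    Column μ becomes i.i.d. N(α/2, alloc_sd); every other column is bitwise
    unchanged.  With α = 5 and SD 0.1 the allocated currents are concentrated
    near 2.5, so the resulting partition for μ is all-engaged.
    """
    if not (0 <= mu < state.frame.P):
        raise ValueError(f"mu={mu} outside [0, P)")
    mean = cfg.alloc_mean if cfg.alloc_mean is not None else alpha / 2.0
    out = state.copy()
    out.eta[:, mu] = rng.normal(mean, cfg.alloc_sd, size=state.Ny) - out.bias
    return out


def _loss_and_grad_U(
    U: np.ndarray, b: np.ndarray, task: TaskSpec, targets: list[int], alpha: float
) -> tuple[float, np.ndarray, np.ndarray]:
    Xt = task.X[:, targets]
    C = U @ Xt + b[:, None]
    Y = phi(C, alpha)
    E = task.W @ Y - task.Z[:, targets]
    G = (task.W.T @ E) * phi_derivative(C, alpha)
    return float(np.sum(E**2)), 2.0 * (G @ Xt.T), E


def learn_gd_U(
    state: WeightState,
    task: TaskSpec,
    targets: list[int] | tuple[int, ...],
    cfg: LearnConfig,
    *,
    alpha: float = 5.0,
) -> tuple[WeightState, LearnReport]:
    """Gradient descent on the synaptic weights U for the target conditions."""
    targets = [int(t) for t in targets]
    if not targets:
        raise ValueError("targets must be nonempty")
    U = state.U.copy()
    b = state.b
    tol = _resolve_tol(cfg, task.Z[:, targets])
    n_obs = task.Z[:, targets].size
    opt = _Adam(cfg.lr) if cfg.optimizer == "adaptive_gd" else None
    steps = 0
    loss, grad, E = _loss_and_grad_U(U, b, task, targets, alpha)
    for steps in range(1, cfg.max_steps + 1):
        rms = np.sqrt(loss / n_obs)
        if rms <= tol:
            steps -= 1
            break
        if not np.isfinite(loss) or loss > 1e15:
            raise FloatingPointError(f"learning diverged at step {steps} (loss={loss:.3e})")
        if np.all(grad == 0.0):
            break  # vanished gradient: all target neurons disengaged
        U += opt.update(grad) if opt else -cfg.lr * grad
        loss, grad, E = _loss_and_grad_U(U, b, task, targets, alpha)
    rms = float(np.sqrt(loss / n_obs))
    per_map = {
        t: float(np.sqrt(np.mean(E[:, j] ** 2))) <= tol for j, t in enumerate(targets)
    }
    return WeightState(U=U, b=b.copy()), LearnReport(
        converged=rms <= tol,
        final_loss=loss,
        final_rms=rms,
        steps_used=steps,
        tol=tol,
        per_mapping_success=per_map,
    )


def learn_gd_eta(
    state: EtaState,
    task: TaskSpec,
    mu: int,
    cfg: LearnConfig,
    *,
    alpha: float = 5.0,
) -> tuple[EtaState, LearnReport]:
    """Gradient descent on η column μ only; all other columns provably untouched."""
    if not (0 <= mu < state.frame.P):
        raise ValueError(f"mu={mu} outside [0, P)")
    out = state.copy()
    col = out.eta[:, mu]
    b = out.bias
    z = task.Z[:, mu]
    W = task.W
    tol = _resolve_tol(cfg, z)
    opt = _Adam(cfg.lr) if cfg.optimizer == "adaptive_gd" else None
    steps = 0
    for steps in range(cfg.max_steps + 1):
        cur = col + b
        err = W @ phi(cur, alpha) - z
        loss = float(np.sum(err**2))
        rms = np.sqrt(loss / z.size)
        if rms <= tol:
            break
        if not np.isfinite(loss) or loss > 1e15:
            raise FloatingPointError(f"eta-learning diverged at step {steps} (loss={loss:.3e})")
        grad = 2.0 * (W.T @ err) * phi_derivative(cur, alpha)
        if np.all(grad == 0.0):
            break
        col += opt.update(grad) if opt else -cfg.lr * grad
    out.learned = frozenset(out.learned | {mu})
    return out, LearnReport(
        converged=rms <= tol,
        final_loss=loss,
        final_rms=float(rms),
        steps_used=steps,
        tol=tol,
        per_mapping_success={mu: rms <= tol},
    )


def _stored_rms(eta_state: EtaState, task: TaskSpec, stored: list[int], alpha: float) -> float:
    cur = eta_state.eta[:, stored] + eta_state.bias[:, None]
    E = task.W @ phi(cur, alpha) - task.Z[:, stored]
    return float(np.sqrt(np.mean(E**2)))


def learnability_protocol(
    cfg: NetworkConfig,
    init_sd_grid: list[float] | np.ndarray,
    use_allocation: bool,
    n_seeds: int,
    *,
    learn_cfg: LearnConfig | None = None,
    learner: str = "U",
    joint_refit: bool = True,
    drift_steps: int = 0,
    drift_cfg: DriftConfig | None = None,
    seed: int = 0,
) -> LearnabilityReport:
    """Count how many mappings can be added sequentially from each initialization.

    For each initial weight SD and each seed, mappings μ = 1, 2, ... (up to
    ``cfg.P``) are added in turn.  Without allocation, each addition refits U
    by gradient descent (jointly over all stored mappings by default, or on
    the new mapping only with ``joint_refit=False``).  With allocation, the
    new η column is first allocated near α/2 and then learned by gradient
    descent in η-coordinates (``learner="eta"``) or in U.  A mapping counts
    as learned when the RMS readout error over *all* stored mappings is
    within tolerance; the protocol stops at the first failure.  Optionally
    the system drifts (readout-preserving) between additions.
    """
    if len(init_sd_grid) == 0:
        raise ValueError("init_sd_grid must be nonempty")
    lc = learn_cfg or LearnConfig(optimizer="adaptive_gd")
    counts = np.zeros((len(init_sd_grid), n_seeds), dtype=int)
    for k in range(n_seeds):
        task = generate_task(cfg, child_seed(seed, f"task-{k}"))
        frame = build_extended_basis(task.X)
        U_unit = substream(seed, f"init-{k}").standard_normal((cfg.Ny, cfg.Nx))
        for g, sd in enumerate(init_sd_grid):
            alloc_rng = substream(seed, f"alloc-{k}-{g}")
            counts[g, k] = _run_sequence(
                task,
                frame,
                sd * U_unit,
                cfg,
                lc,
                use_allocation,
                learner,
                joint_refit,
                drift_steps,
                drift_cfg,
                alloc_rng,
                drift_seed=child_seed(seed, f"drift-{k}-{g}"),
            )
    return LearnabilityReport(
        init_sd_grid=np.asarray(init_sd_grid, dtype=float),
        counts=counts,
        use_allocation=use_allocation,
    )


def _run_sequence(
    task: TaskSpec,
    frame: EtaFrame,
    U0: np.ndarray,
    cfg: NetworkConfig,
    lc: LearnConfig,
    use_allocation: bool,
    learner: str,
    joint_refit: bool,
    drift_steps: int,
    drift_cfg: DriftConfig | None,
    alloc_rng: np.random.Generator,
    drift_seed: int = 0,
) -> int:
    alpha = cfg.alpha
    state = to_eta(U0, frame)
    n_learned = 0
    for nu in range(task.P):
        stored = list(range(nu + 1))
        if use_allocation:
            state = allocate(state, nu, lc, alloc_rng, alpha=alpha)
            if learner == "eta":
                state, rep = learn_gd_eta(state, task, nu, lc, alpha=alpha)
            else:
                ws = WeightState(U=from_eta(state), b=state.bias.copy())
                ws, rep = learn_gd_U(ws, task, [nu], lc, alpha=alpha)
                state = to_eta(ws.U, frame, learned=state.learned | {nu}, bias=ws.b)
        else:
            targets = stored if joint_refit else [nu]
            ws = WeightState(U=from_eta(state), b=state.bias.copy())
            ws, rep = learn_gd_U(ws, task, targets, lc, alpha=alpha)
            state = to_eta(ws.U, frame, learned=state.learned | {nu}, bias=ws.b)
        tol = _resolve_tol(lc, task.Z[:, stored])
        if _stored_rms(state, task, stored, alpha) > tol:
            break
        n_learned = nu + 1
        if drift_steps > 0 and nu < task.P - 1:
            dc = drift_cfg or DriftConfig()
            dc = replace(
                dc,
                n_steps=drift_steps,
                constrained=frozenset(stored),
                seed=drift_seed + nu,
            )
            traj = run_drift(state, task, dc, alpha=alpha)
            state = EtaState(
                eta=traj.eta_snapshots[-1],
                frame=frame,
                learned=state.learned,
                bias=state.bias.copy(),
            )
    return n_learned
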