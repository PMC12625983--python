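"""Restricted diffusion (representational drift) on the weight solution space.

Each drift step perturbs the η-coordinates of the weights so that every
stored input→readout mapping is preserved exactly:

* columns beyond P, and condition columns not yet learned, receive free
  i.i.d. Gaussian increments (unconstrained dimensions);
* inactive coordinates of learned conditions diffuse below the activity
  threshold — a proposal that would cross 0 is clamped exactly to the
  threshold and the neuron joins the engaged set (semiconstrained
  dimensions); saturated coordinates behave symmetrically at α;
* engaged coordinates of a learned condition move only inside the kernel of
  the engaged readout submatrix Wμ, so the readout is untouched; when the
  proposed kernel move would push a neuron across a threshold the whole move
  is rescaled so the first crosser lands exactly on its threshold and
  transitions to the adjacent disengaged set.

A per-postsynaptic-neuron weight-norm bound Umax keeps the diffusion finite:
rows of U that would exceed it have their step rejected (a reflecting
boundary).  Because a multi-neuron kernel increment only preserves the
readout as a whole, rejecting a row also rejects the engaged-block increments
of the conditions that row was engaged in.

All threshold placements are exact assignments (a clamped coordinate is set
to literally ``−b`` or ``α−b``), so set membership needs no epsilon bands and
readouts are conserved to floating-point accuracy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eta import EtaFrame, EtaState, engaged_kernel
from .network import ENGAGED, INACTIVE, SATURATED, TaskSpec

__all__ = [
    "DriftConfig",
    "DriftStep",
    "DriftTrajectory",
    "DriftInvariantError",
    "rescale_to_threshold",
    "drift_step",
    "enforce_norm_bound",
    "run_drift",
    "initial_partition_labels",
]

logger = logging.getLogger(__name__)


class DriftInvariantError(RuntimeError):
    """Raised when drift violates readout conservation beyond tolerance."""


@dataclass(frozen=True)
class DriftConfig:
    """Parameters of the drift simulation.

    sigma is the scale of weight fluctuations per step (SD of the induced
    δU); Umax the per-row weight-norm bound (None = unbounded); constrained
    the set of learned condition columns (None = take them from the state).
    """

    sigma: float = 0.05
    Umax: float | None = None
    n_steps: int = 50_000
    record_every: int = 100
    seed: int | None = None
    constrained: frozenset[int] | None = None
    abort_tol: float = 1e-6

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if self.Umax is not None and not self.Umax > 0:
            raise ValueError("Umax must be positive (or None for unbounded)")
        if self.n_steps < 0:
            raise ValueError("n_steps must be nonnegative")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


@dataclass
class DriftStep:
    """Record of a single accepted drift step."""

    delta_eta: np.ndarray
    transitions: list[tuple[int, int, int, int]]  # (neuron, condition, from, to)
    rejected_rows: list[int]


@dataclass
class DriftTrajectory:
    """Recorded time series of a drift run."""

    times: np.ndarray
    eta_snapshots: np.ndarray  # (T, Ny, Nx)
    engagement_fractions: np.ndarray  # (T, 3): engaged, inactive, saturated
    row_norms: np.ndarray  # (T, Ny)
    readout_error: np.ndarray  # (T,) max |Zhat - Z| over constrained conditions
    conservation: np.ndarray  # (T,) max |Zhat - Zhat0| over constrained conditions
    constrained: tuple[int, ...]
    frame: EtaFrame
    dU_stats: tuple[float, float, int] | None = None  # (sum, sumsq, count)

    def fractions_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.engagement_fractions, columns=["engaged", "inactive", "saturated"]
        )
        df.insert(0, "step", self.times)
        return df

    def row_norms_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.row_norms, columns=[f"neuron_{i}" for i in range(self.row_norms.shape[1])]
        )
        df.insert(0, "step", self.times)
        return df

    @property
    def dU_pooled_sd(self) -> float | None:
        if self.dU_stats is None:
            return None
        s, ss, n = self.dU_stats
        if n == 0:
            return None
        return math.sqrt(max(ss / n - (s / n) ** 2, 0.0))


def rescale_to_threshold(
    eta_engaged: np.ndarray,
    delta: np.ndarray,
    b: np.ndarray,
    alpha: float,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Largest γ ∈ [0, 1] keeping all engaged currents inside [0, α].

    Returns ``(gamma, cross_low, cross_high)`` where the crossers are the
    positions (within the engaged vector) whose current sits exactly on the
    activity threshold (→ inactive) or saturation threshold (→ saturated)
    after the rescaled move γ·delta.  γ = 1 with no crossers when no bound is
    hit.  Several neurons reaching a bound at the same γ all transition.
    """
    cur = np.asarray(eta_engaged, dtype=float) + np.asarray(b, dtype=float)
    delta = np.asarray(delta, dtype=float)
    gi = np.full(cur.shape, np.inf)
    pos = delta > 0
    neg = delta < 0
    gi[pos] = (alpha - cur[pos]) / delta[pos]
    gi[neg] = -cur[neg] / delta[neg]
    gmin = float(gi.min()) if gi.size else np.inf
    if gmin > 1.0:
        return 1.0, np.empty(0, dtype=int), np.empty(0, dtype=int)
    gamma = max(gmin, 0.0)
    hit = gi == gmin
    cross_low = np.flatnonzero(hit & neg)
    cross_high = np.flatnonzero(hit & pos)
    return gamma, cross_low, cross_high


def initial_partition_labels(state: EtaState, alpha: float) -> np.ndarray:
    """Engagement labels for all P condition columns from the current state.

    Boundary convention at initialization: a current exactly at a threshold
    belongs to the adjacent disengaged set.
    """
    C = state.currents()
    labels = np.full(C.shape, ENGAGED, dtype=np.int8)
    labels[C <= 0.0] = INACTIVE
    labels[C >= alpha] = SATURATED
    return labels


def _householder_kernel(w: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the hyperplane orthogonal to a row vector w.

    For a one-dimensional readout the engaged kernel is just w⊥; the trailing
    columns of the Householder reflector mapping w/‖w‖ onto ±e₁ give an
    orthonormal basis without an SVD.
    """
    E = w.size
    nrm = np.linalg.norm(w)
    if nrm == 0.0:
        return np.eye(E)
    u = w / nrm
    if u[0] < 0:
        u = -u
    v = u.copy()
    v[0] += 1.0
    H = (-2.0 / (v @ v)) * np.outer(v, v)
    H[np.diag_indices(E)] += 1.0
    return H[:, 1:]


class _DriftEngine:
    """Mutable stepper: owns the η matrix, labels, and kernel cache."""

    def __init__(
        self,
        state: EtaState,
        task: TaskSpec,
        cfg: DriftConfig,
        alpha: float,
        labels: np.ndarray | None = None,
    ):
        self.frame = state.frame
        self.eta = state.eta.copy()
        self.bias = state.bias.copy()
        self.alpha = float(alpha)
        self.W = task.W
        self.cfg = cfg
        cons = cfg.constrained if cfg.constrained is not None else state.learned
        self.constrained = tuple(sorted(int(m) for m in cons))
        self.Ny, self.Nx = self.eta.shape
        self.col_sd = cfg.sigma * self.frame.scales
        free = np.ones(self.Nx, dtype=bool)
        free[list(self.constrained)] = False
        self.free_cols = np.flatnonzero(free)
        self.free_sd = self.col_sd[self.free_cols]
        st = (
            labels.copy()
            if labels is not None
            else initial_partition_labels(
                EtaState(self.eta, self.frame, bias=self.bias), self.alpha
            )
        )
        self.labels = st
        self.cons_idx = np.asarray(self.constrained, dtype=int)
        self._eg: dict[int, np.ndarray] = {}
        self._K: dict[int, np.ndarray] = {}
        for mu in self.constrained:
            self._refresh(mu)
        self.Umax = math.inf if cfg.Umax is None else float(cfg.Umax)

    def _refresh(self, mu: int) -> None:
        eg = np.flatnonzero(self.labels[:, mu] == ENGAGED)
        self._eg[mu] = eg
        if eg.size == 0:
            self._K[mu] = np.zeros((0, 0))
        elif self.W.shape[0] == 1:
            self._K[mu] = _householder_kernel(self.W[0, eg])
        else:
            self._K[mu] = engaged_kernel(self.W, eg, condition=mu).K

    def step(self, rng: np.random.Generator) -> DriftStep:
        eta, b, alpha = self.eta, self.bias, self.alpha
        eta_prev = eta.copy()
        base = rng.standard_normal((self.Ny, self.Nx)) * self.col_sd[None, :]
        transitions: list[tuple[int, int, int, int]] = []
        touched_engaged: dict[int, np.ndarray] = {}

        if self.free_cols.size:
            eta[:, self.free_cols] += base[:, self.free_cols]

        ci = self.cons_idx
        if ci.size:
            # semiconstrained block, vectorized over all learned conditions
            lab = self.labels[:, ci]
            sub = eta[:, ci]
            prop = sub + base[:, ci]
            curp = prop + b[:, None]
            ia = lab == INACTIVE
            sa = lab == SATURATED
            ia_cross = ia & (curp > 0.0)
            sa_cross = sa & (curp < alpha)
            new = np.where(ia | sa, prop, sub)
            if ia_cross.any():
                new = np.where(ia_cross, np.broadcast_to((-b)[:, None], new.shape), new)
                for i, j in zip(*np.nonzero(ia_cross)):
                    transitions.append((int(i), int(ci[j]), INACTIVE, ENGAGED))
            if sa_cross.any():
                new = np.where(
                    sa_cross, np.broadcast_to((alpha - b)[:, None], new.shape), new
                )
                for i, j in zip(*np.nonzero(sa_cross)):
                    transitions.append((int(i), int(ci[j]), SATURATED, ENGAGED))
            eta[:, ci] = new

            pool = rng.standard_normal((self.Ny, ci.size))
            for k, mu in enumerate(self.constrained):
                K = self._K[mu]
                m = K.shape[1]
                if not m:
                    continue
                eg = self._eg[mu]
                d = K @ (pool[:m, k] * self.col_sd[mu])
                col = eta[:, mu]
                cur = col[eg] + b[eg]
                ad = np.abs(d)
                dist = np.where(d > 0, alpha - cur, cur)
                gi = np.divide(dist, ad, out=np.full(eg.size, np.inf), where=ad > 0)
                gmin = gi.min()
                touched_engaged[mu] = eg
                if gmin > 1.0:
                    col[eg] = col[eg] + d
                else:
                    gamma = gmin if gmin > 0.0 else 0.0
                    col[eg] = col[eg] + gamma * d
                    for pos in np.flatnonzero(gi == gmin):
                        i = int(eg[pos])
                        if d[pos] < 0:
                            col[i] = -b[i]
                            transitions.append((i, mu, ENGAGED, INACTIVE))
                        else:
                            col[i] = alpha - b[i]
                            transitions.append((i, mu, ENGAGED, SATURATED))

        rejected: list[int] = []
        if math.isfinite(self.Umax):
            rejected = self._enforce_bound(eta_prev, transitions, touched_engaged)

        if transitions:
            for i, mu, _frm, to in transitions:
                self.labels[i, mu] = to
            for mu in {mu for _i, mu, _f, _t in transitions}:
                self._refresh(mu)

        return DriftStep(
            delta_eta=eta - eta_prev, transitions=transitions, rejected_rows=rejected
        )

    def _enforce_bound(
        self,
        eta_prev: np.ndarray,
        transitions: list[tuple[int, int, int, int]],
        touched_engaged: dict[int, np.ndarray],
    ) -> list[int]:
        eta = self.eta
        rejected: set[int] = set()
        reverted_conditions: set[int] = set()
        for _ in range(self.Ny + 1):
            norms = np.linalg.norm(eta @ self.frame.Xinv, axis=1)
            bad = [
                int(i) for i in np.flatnonzero(norms > self.Umax) if i not in rejected
            ]
            if not bad:
                break
            for i in bad:
                eta[i, :] = eta_prev[i, :]
                rejected.add(i)
            # a reverted row invalidates the kernel increments it took part in
            for mu, eg in touched_engaged.items():
                if mu in reverted_conditions:
                    continue
                if any(i in rejected for i in eg):
                    eta[eg, mu] = eta_prev[eg, mu]
                    reverted_conditions.add(mu)
        if rejected:
            transitions[:] = [
                (i, mu, f, t)
                for (i, mu, f, t) in transitions
                if i not in rejected and not (mu in reverted_conditions and f == ENGAGED)
            ]
        return sorted(rejected)

    def snapshot_readout(self, conditions: list[int]) -> np.ndarray:
        cur = self.eta[:, conditions] + self.bias[:, None]
        Y = np.clip(cur, 0.0, self.alpha)
        return self.W @ Y

    def state(self, learned: frozenset[int]) -> EtaState:
        return EtaState(
            eta=self.eta.copy(), frame=self.frame, learned=learned, bias=self.bias.copy()
        )


def drift_step(
    state: EtaState,
    labels: np.ndarray,
    task: TaskSpec,
    cfg: DriftConfig,
    rng: np.random.Generator,
    *,
    alpha: float = 5.0,
) -> tuple[EtaState, np.ndarray, DriftStep]:
    """One drift step as a pure function: returns (new state, new labels, record).

    ``labels`` are the engagement labels for the P condition columns (see
    :func:`initial_partition_labels`); only the constrained columns matter.
    For long runs prefer :func:`run_drift`, which keeps the kernel cache
    across steps.
    """
    eng = _DriftEngine(state, task, cfg, alpha, labels=labels)
    rec = eng.step(rng)
    return eng.state(state.learned), eng.labels.copy(), rec


def enforce_norm_bound(
    candidate: EtaState, previous: EtaState, frame: EtaFrame, Umax: float | None
) -> EtaState:
    """Per-row rejection: rows of U = η·Xinv over the bound revert to ``previous``.

    This is the stand-alone (stateless) form; inside a drift step the same
    rule additionally reverts kernel increments shared with a rejected row.
    """
    if Umax is None or not math.isfinite(Umax):
        return candidate
    eta = candidate.eta.copy()
    norms = np.linalg.norm(eta @ frame.Xinv, axis=1)
    bad = norms > Umax
    eta[bad, :] = previous.eta[bad, :]
    return EtaState(
        eta=eta, frame=frame, learned=candidate.learned, bias=candidate.bias.copy()
    )


def run_drift(
    state: EtaState,
    task: TaskSpec,
    cfg: DriftConfig,
    *,
    alpha: float = 5.0,
    rng: np.random.Generator | None = None,
    track_dU: bool = False,
) -> DriftTrajectory:
    """Iterate drift steps, recording every ``record_every`` steps.

    The initial state must already satisfy the constrained conditions'
    readouts; the run aborts with :class:`DriftInvariantError` if the stored
    readouts move by more than ``cfg.abort_tol`` (relative to the readout
    scale) at any recorded time.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    eng = _DriftEngine(state, task, cfg, alpha)
    cons = list(eng.constrained)
    Zhat0 = eng.snapshot_readout(cons)
    scale = max(1.0, float(np.max(np.abs(Zhat0))) if Zhat0.size else 1.0)
    Zcons = task.Z[:, cons] if cons else np.zeros_like(Zhat0)

    times, etas, fracs, norms, rerr, consv = [], [], [], [], [], []
    dU_sum = dU_sumsq = 0.0
    dU_n = 0

    def record(t: int) -> None:
        times.append(t)
        etas.append(eng.eta.copy())
        lab = eng.labels[:, cons] if cons else eng.labels
        fracs.append(
            [
                float(np.mean(lab == ENGAGED)),
                float(np.mean(lab == INACTIVE)),
                float(np.mean(lab == SATURATED)),
            ]
        )
        U = eng.eta @ eng.frame.Xinv
        norms.append(np.linalg.norm(U, axis=1))
        Zhat = eng.snapshot_readout(cons)
        rerr.append(float(np.max(np.abs(Zhat - Zcons))) if cons else 0.0)
        dev = float(np.max(np.abs(Zhat - Zhat0))) if cons else 0.0
        consv.append(dev)
        if dev > cfg.abort_tol * scale:
            raise DriftInvariantError(
                f"stored readout moved by {dev:.3e} (> {cfg.abort_tol:.1e} x scale "
                f"{scale:.3g}) at step {t}; constrained={cons}"
            )

    record(0)
    for t in range(1, cfg.n_steps + 1):
        rec = eng.step(rng)
        if track_dU:
            dU = rec.delta_eta @ eng.frame.Xinv
            dU_sum += float(dU.sum())
            dU_sumsq += float((dU * dU).sum())
            dU_n += dU.size
        if t % cfg.record_every == 0 or t == cfg.n_steps:
            record(t)

    logger.info(
        "drift run: %d steps, %d records, final engaged fraction %.3f",
        cfg.n_steps,
        len(times),
        fracs[-1][0],
    )
    return DriftTrajectory(
        times=np.asarray(times),
        eta_snapshots=np.asarray(etas),
        engagement_fractions=np.asarray(fracs),
        row_norms=np.asarray(norms),
        readout_error=np.asarray(rerr),
        conservation=np.asarray(consv),
        constrained=tuple(cons),
        frame=eng.frame,
        dU_stats=(dU_sum, dU_sumsq, dU_n) if track_dU else None,
    )
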