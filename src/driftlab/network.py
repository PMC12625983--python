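"""Network definition, activation function, forward map, and task generation.

The model is a single-hidden-layer network: ``Nx`` input neurons drive ``Ny``
representation neurons through plastic synaptic weights ``U`` (plus bias
``b``), and a *fixed* linear readout ``W`` maps the representation to ``Nz``
behavioral outputs.  Activity is given by the clipped-threshold-linear
function Φ: zero below the activity threshold 0, linear in between, clamped
at the saturation threshold α.  Across ``P`` input conditions (columns of
``X``) the network must realize target readouts ``Z``, i.e. ``Z = W·Φ(U·X+B)``.

Per condition, each representation neuron is classified by its input current:
*inactive* (current ≤ 0), *saturated* (current ≥ α), or *engaged* (strictly in
between).  Engaged neurons respond to current perturbations; disengaged ones
do not — this classification drives both the drift dynamics and the
learnability/robustness analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkConfig",
    "TaskSpec",
    "WeightState",
    "ActivitySnapshot",
    "EngagementPartition",
    "INACTIVE",
    "ENGAGED",
    "SATURATED",
    "phi",
    "phi_derivative",
    "forward",
    "partition_neurons",
    "generate_task",
]

logger = logging.getLogger(__name__)

# Engagement labels (per neuron, per condition).
INACTIVE, ENGAGED, SATURATED = 0, 1, 2


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and activation parameters.

    Defaults are the standard simulation sizes: 15 input neurons, 12
    representation neurons, a one-dimensional readout, 8 input conditions,
    and saturation threshold α = 5.
    """

    Nx: int = 15
    Ny: int = 12
    Nz: int = 1
    P: int = 8
    alpha: float = 5.0

    def __post_init__(self) -> None:
        for name in ("Nx", "Ny", "Nz", "P"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.Nz > self.Ny:
            raise ValueError(f"Nz={self.Nz} must not exceed Ny={self.Ny}")
        if self.P > self.Nx:
            raise ValueError(
                f"P={self.P} must not exceed Nx={self.Nx}: the solution-space "
                "construction requires at least as many input neurons as conditions"
            )
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")


@dataclass(frozen=True)
class TaskSpec:
    """Fixed anchors of the solution space: inputs, readout weights, targets.

    ``X`` is Nx×P with full column rank, ``W`` is the fixed Nz×Ny readout,
    ``Z`` the Nz×P target readouts.  When a teacher ``T`` is present the
    targets satisfy ``Z = W·Φ(T·X + B)`` exactly.
    """

    X: np.ndarray
    W: np.ndarray
    Z: np.ndarray
    T: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "X", np.asarray(self.X, dtype=float))
        object.__setattr__(self, "W", np.asarray(self.W, dtype=float))
        object.__setattr__(self, "Z", np.asarray(self.Z, dtype=float))
        if self.T is not None:
            object.__setattr__(self, "T", np.asarray(self.T, dtype=float))
        if self.X.ndim != 2 or self.W.ndim != 2 or self.Z.ndim != 2:
            raise ValueError("X, W and Z must be 2-D arrays")
        Nx, P = self.X.shape
        Nz, Ny = self.W.shape
        if self.Z.shape != (Nz, P):
            raise ValueError(f"Z has shape {self.Z.shape}, expected {(Nz, P)}")
        if np.linalg.matrix_rank(self.X) < P:
            raise ValueError("X must have full column rank")

    @property
    def Nx(self) -> int:
        return self.X.shape[0]

    @property
    def P(self) -> int:
        return self.X.shape[1]

    @property
    def Ny(self) -> int:
        return self.W.shape[1]

    @property
    def Nz(self) -> int:
        return self.W.shape[0]


@dataclass
class WeightState:
    """Plastic synaptic weights ``U`` (Ny×Nx) and bias ``b`` (Ny,)."""

    U: np.ndarray
    b: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        if self.U.ndim != 2:
            raise ValueError("U must be 2-D")
        if self.b is None:
            self.b = np.zeros(self.U.shape[0])
        else:
            self.b = np.asarray(self.b, dtype=float)
        if self.b.shape != (self.U.shape[0],):
            raise ValueError(f"b has shape {self.b.shape}, expected {(self.U.shape[0],)}")
        if not (np.all(np.isfinite(self.U)) and np.all(np.isfinite(self.b))):
            raise ValueError("weights and biases must be finite")


@dataclass(frozen=True)
class ActivitySnapshot:
    """Input currents ``C = UX+B``, activities ``Y = Φ(C)``, readouts ``Zhat = WY``."""

    C: np.ndarray
    Y: np.ndarray
    Zhat: np.ndarray


@dataclass(frozen=True)
class EngagementPartition:
    """Per-(neuron, condition) engagement labels.

    ``labels[i, mu]`` is one of INACTIVE/ENGAGED/SATURATED.  The three sets
    partition the neuron population for every condition.  ``index_map(mu)``
    returns the i′ map from neuron index to its (0-based) position within the
    ordered engaged set of condition mu.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels))
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D (Ny × P)")

    def engaged(self, mu: int) -> np.ndarray:
        return np.flatnonzero(self.labels[:, mu] == ENGAGED)

    def inactive(self, mu: int) -> np.ndarray:
        return np.flatnonzero(self.labels[:, mu] == INACTIVE)

    def saturated(self, mu: int) -> np.ndarray:
        return np.flatnonzero(self.labels[:, mu] == SATURATED)

    def index_map(self, mu: int) -> dict[int, int]:
        return {int(i): pos for pos, i in enumerate(self.engaged(mu))}

    def fractions(self, conditions: np.ndarray | list[int] | None = None) -> dict[str, float]:
        """Pooled engaged/inactive/saturated fractions over (neuron, condition) pairs."""
        lab = self.labels if conditions is None else self.labels[:, list(conditions)]
        n = lab.size
        if n == 0:
            return {"engaged": np.nan, "inactive": np.nan, "saturated": np.nan}
        return {
            "engaged": float(np.mean(lab == ENGAGED)),
            "inactive": float(np.mean(lab == INACTIVE)),
            "saturated": float(np.mean(lab == SATURATED)),
        }


def phi(v: np.ndarray | float, alpha: float) -> np.ndarray | float:
    """Clipped-threshold-linear activation: 0 for v ≤ 0, v on (0, α), α for v ≥ α."""
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite input current")
    out = np.clip(arr, 0.0, alpha)
    return float(out) if np.isscalar(v) or arr.ndim == 0 else out


def phi_derivative(v: np.ndarray | float, alpha: float) -> np.ndarray | float:
    """Derivative of Φ: 1 strictly inside (0, α), 0 elsewhere.

    Exactly at the thresholds the derivative is taken as 0 (the disengaged
    side), so neurons clamped at a threshold contribute no gradient.
    """
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite input current")
    out = ((arr > 0.0) & (arr < alpha)).astype(float)
    return float(out) if np.isscalar(v) or arr.ndim == 0 else out


def forward(weights: WeightState, task: TaskSpec, cfg: NetworkConfig) -> ActivitySnapshot:
    """Evaluate the network: C = U·X + B, Y = Φ(C), Zhat = W·Y."""
    U, b = weights.U, weights.b
    if U.shape != (cfg.Ny, cfg.Nx):
        raise ValueError(f"U has shape {U.shape}, expected {(cfg.Ny, cfg.Nx)}")
    if task.X.shape[0] != cfg.Nx or task.W.shape != (cfg.Nz, cfg.Ny):
        raise ValueError("task shapes inconsistent with network config")
    C = U @ task.X + b[:, None]
    Y = phi(C, cfg.alpha)
    return ActivitySnapshot(C=C, Y=Y, Zhat=task.W @ Y)


def partition_neurons(snapshot: ActivitySnapshot, cfg: NetworkConfig) -> EngagementPartition:
    """Classify neurons by input current: inactive ≤ 0 < engaged < α ≤ saturated.

    Currents exactly at a threshold are assigned to the adjacent disengaged
    set (boundary → disengaged convention at initialization; the stateful
    transition rules during drift may override this).
    """
    C = snapshot.C
    if not np.all(np.isfinite(C)):
        raise ValueError("non-finite currents")
    labels = np.full(C.shape, ENGAGED, dtype=np.int8)
    labels[C <= 0.0] = INACTIVE
    labels[C >= cfg.alpha] = SATURATED
    return EngagementPartition(labels=labels)


def generate_task(
    cfg: NetworkConfig,
    seed: int,
    *,
    teacher_sd: float = 1.0,
    input_sd: float = 1.0,
    readout_sd: float = 10.0,
    bias: np.ndarray | None = None,
) -> TaskSpec:
    """Draw a random task: X ~ N(0,1), W ~ N(0,10), teacher T ~ N(0,1).

    Targets are produced by the teacher network through the same activation
    and readout: ``Z = W·Φ(T·X + B)``.  Reproducible given ``seed``; a
    rank-deficient X draw (measure zero) is resampled with a warning.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for attempt in range(10):
        X = rng.normal(0.0, input_sd, size=(cfg.Nx, cfg.P))
        if np.linalg.matrix_rank(X) == cfg.P:
            break
        warnings.warn(f"rank-deficient X draw (attempt {attempt + 1}); resampling")
    else:  # pragma: no cover - probability zero
        raise RuntimeError("could not sample a full-column-rank X")
    W = rng.normal(0.0, readout_sd, size=(cfg.Nz, cfg.Ny))
    T = rng.normal(0.0, teacher_sd, size=(cfg.Ny, cfg.Nx))
    b = np.zeros(cfg.Ny) if bias is None else np.asarray(bias, dtype=float)
    Z = W @ phi(T @ X + b[:, None], cfg.alpha)
    return TaskSpec(X=X, W=W, Z=Z, T=T, seed=seed)
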