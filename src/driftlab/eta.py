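"""The η-coordinate system on synaptic weights.

For each postsynaptic neuron the incoming weights are re-expressed in the
basis ``Xext = [X | Q]`` where ``Q`` is an orthonormal completion spanning the
orthogonal complement of the column space of the inputs ``X``.  In these
coordinates, ``η = U·Xext``:

* columns 1..P of η are exactly the input currents ``U·X`` for the P
  conditions (the constrained block), and
* columns P+1..Nx live in the kernel of X — moving them changes the weights
  without changing any input current (the unconstrained block, of dimension
  Ny·(Nx−P) over the whole weight matrix).

The frame also carries per-column noise scales ``s_μ = 1/‖row μ of Xext⁻¹‖``,
chosen so that independent per-coordinate η noise with SD σ·s_μ induces
weight increments δU whose pooled SD is σ (equal-variance weight
fluctuations).

Drift of engaged activity for condition μ must not change the readout, so it
is confined to the kernel of the *engaged submatrix* ``Wμ`` (the readout
columns of the engaged neurons); :func:`engaged_kernel` builds an orthonormal
basis of that kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import null_space

__all__ = [
    "EtaFrame",
    "EtaState",
    "KernelBasis",
    "build_extended_basis",
    "to_eta",
    "from_eta",
    "noise_scales",
    "engaged_kernel",
]

_ATOL = 1e-10


def _fix_signs(Q: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive (ties: first)."""
    if Q.size == 0:
        return Q
    idx = np.argmax(np.abs(Q), axis=0)
    signs = np.sign(Q[idx, np.arange(Q.shape[1])])
    signs[signs == 0] = 1.0
    return Q * signs


@dataclass(frozen=True)
class EtaFrame:
    """Extended basis ``Xext`` (first P columns = X), its inverse, and noise scales."""

    Xext: np.ndarray
    Xinv: np.ndarray
    scales: np.ndarray
    P: int

    @property
    def Nx(self) -> int:
        return self.Xext.shape[0]

    @property
    def X(self) -> np.ndarray:
        return self.Xext[:, : self.P]


@dataclass
class EtaState:
    """Weights in η-coordinates.

    ``eta`` is Ny×Nx; ``learned`` is the set of (0-based) condition columns
    currently constrained by a stored mapping; ``bias`` is the per-neuron
    bias, so the input current of neuron i under condition μ is
    ``eta[i, μ] + bias[i]``.
    """

    eta: np.ndarray
    frame: EtaFrame
    learned: frozenset[int] = frozenset()
    bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=float)
        if self.eta.ndim != 2 or self.eta.shape[1] != self.frame.Nx:
            raise ValueError(
                f"eta has shape {self.eta.shape}, expected (Ny, {self.frame.Nx})"
            )
        self.learned = frozenset(int(m) for m in self.learned)
        if any(m < 0 or m >= self.frame.P for m in self.learned):
            raise ValueError("learned columns must lie in [0, P)")
        if self.bias is None:
            self.bias = np.zeros(self.eta.shape[0])
        else:
            self.bias = np.asarray(self.bias, dtype=float)

    @property
    def Ny(self) -> int:
        return self.eta.shape[0]

    def currents(self, mu: int | None = None) -> np.ndarray:
        """Input currents η[:, μ] + b (all P condition columns if mu is None)."""
        if mu is None:
            return self.eta[:, : self.frame.P] + self.bias[:, None]
        return self.eta[:, mu] + self.bias

    def copy(self) -> "EtaState":
        return EtaState(
            eta=self.eta.copy(), frame=self.frame, learned=self.learned, bias=self.bias.copy()
        )


@dataclass(frozen=True)
class KernelBasis:
    """Column-orthonormal basis of ker(Wμ) for the ordered engaged set of μ."""

    condition: int
    engaged_list: tuple[int, ...]
    K: np.ndarray

    @property
    def dim(self) -> int:
        return self.K.shape[1]


def build_extended_basis(X: np.ndarray) -> EtaFrame:
    """Construct ``Xext = [X | Q]`` with Q an orthonormal basis of col(X)⊥.

    The completion is computed by a deterministic SVD factorization with the
    sign of each column fixed so that its largest-magnitude entry is
    positive.  The inverse and per-column noise scales are cached on the
    frame.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    Nx, P = X.shape
    if np.linalg.matrix_rank(X) < P:
        raise ValueError("X must have full column rank")
    if P < Nx:
        Q = _fix_signs(null_space(X.T))
        if Q.shape != (Nx, Nx - P):  # pragma: no cover - guarded by rank check
            raise ValueError("unexpected completion dimension")
        Xext = np.hstack([X, Q])
    else:
        Xext = X.copy()
    Xinv = np.linalg.inv(Xext)
    if np.max(np.abs(Xext @ Xinv - np.eye(Nx))) > _ATOL:
        raise ValueError("Xext is too ill-conditioned to invert reliably")
    scales = 1.0 / np.linalg.norm(Xinv, axis=1)
    return EtaFrame(Xext=Xext, Xinv=Xinv, scales=scales, P=P)


def to_eta(
    U: np.ndarray,
    frame: EtaFrame,
    *,
    learned: frozenset[int] | set[int] = frozenset(),
    bias: np.ndarray | None = None,
) -> EtaState:
    """η = U·Xext.  Columns 1..P equal the input currents U·X."""
    U = np.asarray(U, dtype=float)
    if U.ndim != 2 or U.shape[1] != frame.Nx:
        raise ValueError(f"U has shape {U.shape}, expected (Ny, {frame.Nx})")
    return EtaState(eta=U @ frame.Xext, frame=frame, learned=frozenset(learned), bias=bias)


def from_eta(state: EtaState) -> np.ndarray:
    """Recover the physical weights, U = η·Xext⁻¹."""
    return state.eta @ state.frame.Xinv


def noise_scales(frame: EtaFrame, sigma: float) -> np.ndarray:
    """Per-column SDs σ·s_μ of the η-coordinate noise.

    ``s_μ = 1/‖row μ of Xext⁻¹‖₂`` generates equal-variance weight
    fluctuations: independent η noise at these scales induces δU = δη·Xext⁻¹
    that is approximately zero-mean normal with pooled SD σ in physical
    coordinates.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    return sigma * frame.scales


def engaged_kernel(
    W: np.ndarray, engaged_list: np.ndarray | list[int], *, condition: int = -1
) -> KernelBasis:
    """Orthonormal kernel basis of the engaged submatrix Wμ = W[:, Eμ].

    Returns an |Eμ|×(|Eμ|−Nz) column-orthonormal K with Wμ·K = 0 (empty when
    |Eμ| ≤ Nz and Wμ has full column rank).  Drift of engaged activity
    confined to span(K) leaves the readout W·Y unchanged.
    """
    W = np.asarray(W, dtype=float)
    engaged_list = tuple(int(i) for i in engaged_list)
    if len(engaged_list) == 0:
        raise ValueError("engaged_list must be nonempty")
    Wmu = W[:, list(engaged_list)]
    K = _fix_signs(null_space(Wmu))
    return KernelBasis(condition=condition, engaged_list=engaged_list, K=K)
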