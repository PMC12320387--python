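"""Inter-electrode adjacency: Gaussian-kernel initialization and the
mutable state carried by the dynamic attention layer.

The classical graph construction weights each electrode pair by a Gaussian
kernel of inter-electrode distance,

    w_ij = exp(-dist(i, j)^2 / (2 theta^2))  if dist(i, j) <= tau, else 0,

with kernel width ``theta`` and connection radius ``tau`` fixed up front.
The dynamic model keeps this matrix only as an initial value: a buffer
``w`` starts at ``w0`` and is pulled toward freshly computed attention
scores by a momentum update during training (see
:mod:`dgat.layers`), so the learned connectivity supersedes the
predefined structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import Montage, electrode_distances

__all__ = [
    "AdjacencyState",
    "init_adjacency_gaussian",
    "make_adjacency_state",
    "default_theta",
    "adjacency_for_montage",
    "export_adjacency_csv",
]


def init_adjacency_gaussian(
    distances: np.ndarray, theta: float, tau: float = np.inf
) -> np.ndarray:
    """Gaussian-kernel adjacency with a hard distance cutoff.

    ``distances`` must be symmetric and nonnegative with a zero diagonal;
    the result is symmetric with diagonal exactly 1 and entries in [0, 1].
    ``tau = inf`` keeps the graph fully connected.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < 0) or np.any(np.diag(d) != 0):
        raise ValueError("distances must be nonnegative with zero diagonal")
    if theta <= 0:
        raise ValueError("theta must be positive")
    if tau <= 0:
        raise ValueError("tau must be positive")
    w = np.exp(-(d**2) / (2 * theta**2))
    w[d > tau] = 0.0
    np.fill_diagonal(w, 1.0)
    return w


def default_theta(distances: np.ndarray) -> float:
    """Kernel width default: mean off-diagonal inter-electrode distance."""
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if n < 2:
        return 1.0
    off = d[~np.eye(n, dtype=bool)]
    return float(off.mean())


def adjacency_for_montage(
    montage: Montage, theta: float | None = None, tau: float = np.inf
) -> np.ndarray:
    """Gaussian-kernel adjacency from a montage's electrode geometry."""
    d = electrode_distances(montage)
    if theta is None:
        theta = default_theta(d)
    return init_adjacency_gaussian(d, theta, tau)


@dataclass
class AdjacencyState:
    """Initial adjacency plus the momentum-updated dynamic buffer.

    ``w`` starts equal to ``w0`` and, when ``trainable``, is moved toward
    the layer's attention scores by ``w <- beta*w + (1-beta)*e`` on each
    training step. ``beta`` is the momentum parameter (default 0.5). The
    buffer is not symmetrized: attention is directed, so ``w`` may become
    asymmetric even though ``w0`` is symmetric.
    """

    w0: np.ndarray
    beta: float = 0.5
    trainable: bool = True
    w: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        w0 = np.asarray(self.w0, dtype=float)
        if w0.ndim != 2 or w0.shape[0] != w0.shape[1]:
            raise ValueError("w0 must be square")
        if not np.allclose(w0, w0.T, atol=1e-9):
            raise ValueError("w0 must be symmetric")
        if np.any(w0 < -1e-12) or np.any(w0 > 1 + 1e-12):
            raise ValueError("w0 entries must lie in [0, 1]")
        if not np.allclose(np.diag(w0), 1.0, atol=1e-9):
            raise ValueError("w0 diagonal must be 1")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")
        self.w0 = w0
        self.w = w0.copy()

    @property
    def n(self) -> int:
        return self.w0.shape[0]

    def mask(self) -> np.ndarray:
        """Neighborhoods implied by the initial adjacency (nonzero entries).

        The diagonal is always included: every node attends to itself.
        """
        m = self.w0 > 0
        np.fill_diagonal(m, True)
        return m

    def reset(self) -> None:
        self.w = self.w0.copy()


def make_adjacency_state(
    w0: np.ndarray, beta: float = 0.5, trainable: bool = True
) -> AdjacencyState:
    """Validated construction of an :class:`AdjacencyState` from ``w0``."""
    return AdjacencyState(w0=w0, beta=beta, trainable=trainable)


def export_adjacency_csv(
    w: np.ndarray, channel_labels: tuple[str, ...], path
) -> None:
    """N x N matrix as CSV with channel labels as header and index."""
    import pandas as pd

    pd.DataFrame(np.asarray(w), index=channel_labels, columns=channel_labels).to_csv(
        path
    )
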