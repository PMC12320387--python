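"""Post-hoc interpretation: learned connectivity and attention topography.

After training, the first dynamic layer's post-update attention
coefficients form an N x N row-stochastic matrix per sample. Averaging
them over all samples of one emotion class gives that class's *learned
connectivity*; summing its columns (attention received by each electrode)
and renormalizing gives a per-channel *attention topography* suitable for
scalp maps. The first layer is used by default because it sits closest to
electrode space; deeper layers are available via ``layer=``.

These are one faithful reading of common connectivity/topography analyses
for attention models; on synthetic data with planted coupling the
connectivity is validated against the ground-truth mixing matrix with a
rank statistic under a permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import DGATResults
from .montage import DEFeatureTensor

__all__ = [
    "ClassConnectivity",
    "AttentionTopography",
    "class_connectivity",
    "attention_topography",
    "export_embedding_inputs",
    "connectivity_rank_test",
]


@dataclass(frozen=True)
class ClassConnectivity:
    """Class-conditional mean attention matrix (rows attend to columns)."""

    class_label: int
    matrix: np.ndarray  # (N, N)
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("need at least one sample")


@dataclass(frozen=True)
class AttentionTopography:
    """Per-channel attention-received weights, nonnegative, summing to 1."""

    class_label: int
    per_channel: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        w = np.asarray(self.per_channel, dtype=float)
        if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("weights must be nonnegative and sum to 1")


def _class_attention(
    results: DGATResults, features: DEFeatureTensor, class_label: int, layer: int
) -> tuple[np.ndarray, int]:
    idx = np.flatnonzero(features.labels == class_label)
    if idx.size == 0:
        raise ValueError(f"no samples with class {class_label}")
    alphas = []
    # batch to keep the (S, N, N) attention stacks small
    for start in range(0, idx.size, 256):
        sl = idx[start : start + 256]
        alphas.append(results.attention(features.values[sl], layer=layer))
    return np.concatenate(alphas).mean(axis=0), int(idx.size)


def class_connectivity(
    results: DGATResults,
    features: DEFeatureTensor,
    class_label: int,
    layer: int = 0,
) -> ClassConnectivity:
    """Mean post-update attention over one class's samples (head-averaged)."""
    mat, n = _class_attention(results, features, class_label, layer)
    return ClassConnectivity(class_label=int(class_label), matrix=mat, n_samples=n)


def attention_topography(
    results: DGATResults,
    features: DEFeatureTensor,
    class_label: int,
    layer: int = 0,
    direction: str = "received",
) -> AttentionTopography:
    """Per-channel attention weights from the class connectivity.

    ``direction="received"`` (default) sums columns — how much attention a
    channel attracts; ``"given"`` sums rows. Weights are renormalized to
    sum to 1, so a uniform attention matrix yields 1/N everywhere.
    """
    conn = class_connectivity(results, features, class_label, layer)
    return topography_from_connectivity(conn, direction)


def topography_from_connectivity(
    conn: ClassConnectivity, direction: str = "received"
) -> AttentionTopography:
    if direction == "received":
        w = conn.matrix.sum(axis=0)
    elif direction == "given":
        w = conn.matrix.sum(axis=1)
    else:
        raise ValueError("direction must be 'received' or 'given'")
    return AttentionTopography(conn.class_label, w / w.sum())


def export_embedding_inputs(features: DEFeatureTensor, path) -> None:
    """Flat sample x feature CSV (plus label column) for embedding tools."""
    import pandas as pd

    flat = features.flat()
    cols = [
        f"{ch}_{low:g}-{high:g}Hz"
        for ch in features.montage.channel_labels
        for low, high in features.band_edges
    ]
    df = pd.DataFrame(flat, columns=cols)
    df["label"] = features.labels
    df.to_csv(path, index=False)


def connectivity_rank_test(
    learned: np.ndarray,
    planted: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman correlation of off-diagonal weights against planted coupling.

    Returns ``(rho, p)`` where ``p`` is a one-sided permutation p-value
    under random relabeling of the off-diagonal entries (the planted
    matrix is symmetrized and the diagonal excluded, since self-attention
    is uninformative about coupling).
    """
    from scipy import stats

    learned = np.asarray(learned, dtype=float)
    planted = np.asarray(planted, dtype=float)
    n = learned.shape[0]
    off = ~np.eye(n, dtype=bool)
    x = ((learned + learned.T) / 2)[off]
    y = ((planted + planted.T) / 2)[off]
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    for i in range(n_permutations):
        null[i] = np.corrcoef(rx, rng.permutation(ry))[0, 1]
    p = float((1 + np.sum(null >= rho)) / (1 + n_permutations))
    return rho, p
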