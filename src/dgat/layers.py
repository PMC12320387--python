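"""Static and dynamic graph-attention layers, with analytic gradients.

A static graph-attention (GAT) head projects node features through a shared
matrix ``W`` (F' x F), scores each ordered electrode pair with a learned
attention vector ``a`` (length 2F'),

    e_ij = LeakyReLU(a^T [W h_i || W h_j]),

row-softmaxes the scores over each node's neighborhood into coefficients
``alpha_ij``, and aggregates ``h'_i = act(sum_j alpha_ij W h_j)``. K heads
run in parallel and their outputs are concatenated (or averaged for a
final layer).

The dynamic layer keeps a persistent adjacency buffer ``w`` (initialized
from the Gaussian-kernel graph) and, on every training forward pass,
blends it with the fresh scores using a momentum parameter ``beta``:

    w_ij <- beta * w_ij + (1 - beta) * e_ij,

then softmax-normalizes the *updated* weights into ``alpha``. With
``beta = 1`` the buffer never moves and the layer reduces to a static
layer whose attention logits are the frozen buffer; with ``beta = 0`` the
buffer is ignored and the layer is exactly the static GAT above. The
buffer is shared across attention heads by default (heads share the
structural prior and differ in their feature projections); a per-head
buffer is available via ``per_head_adjacency``.

Everything here is plain NumPy. ``DGATLayer.backward`` implements the
analytic gradients of the full forward pass (verified against central
finite differences in the test suite), which keeps the package free of
any deep-learning framework dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .graph import AdjacencyState

__all__ = [
    "GATLayerParams",
    "NeighborhoodSpec",
    "DGATLayer",
    "attention_scores",
    "normalize_attention",
    "gat_head_forward",
    "multi_head_forward",
    "dynamic_update",
    "dgat_layer_forward",
]

#: Additive sentinel for masked (non-neighbor) pairs before the softmax.
#: A large negative finite value keeps gradients defined, unlike -inf.
MASK_SENTINEL = -1e9


def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _leaky_grad(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, 1.0, slope)


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


_ACTIVATIONS = {
    "elu": (_elu, _elu_grad),
    "identity": (lambda x: x, lambda x: np.ones_like(x)),
}


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[-1], shape[-2] if len(shape) > 1 else shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


@dataclass
class GATLayerParams:
    """Per-head projection matrices and attention vectors of one layer.

    ``W_heads`` is (K, F', F); ``a_heads`` is (K, 2F'). The output width is
    K*F' when ``concat`` is true, F' when heads are averaged.
    """

    W_heads: np.ndarray
    a_heads: np.ndarray
    leaky_slope: float = 0.2
    concat: bool = True

    def __post_init__(self) -> None:
        self.W_heads = np.asarray(self.W_heads, dtype=float)
        self.a_heads = np.asarray(self.a_heads, dtype=float)
        if self.W_heads.ndim != 3:
            raise ValueError("W_heads must be (K, F', F)")
        k, fp, _ = self.W_heads.shape
        if self.a_heads.shape != (k, 2 * fp):
            raise ValueError("a_heads must be (K, 2*F')")
        if k < 1:
            raise ValueError("need at least one head")

    @property
    def n_heads(self) -> int:
        return self.W_heads.shape[0]

    @property
    def f_out(self) -> int:
        return self.W_heads.shape[1]

    @property
    def f_in(self) -> int:
        return self.W_heads.shape[2]

    @property
    def out_dim(self) -> int:
        return self.n_heads * self.f_out if self.concat else self.f_out

    @classmethod
    def init(
        cls,
        rng: np.random.Generator,
        n_heads: int,
        f_in: int,
        f_out: int,
        leaky_slope: float = 0.2,
        concat: bool = True,
    ) -> "GATLayerParams":
        return cls(
            W_heads=glorot_uniform(rng, (n_heads, f_out, f_in)),
            a_heads=glorot_uniform(rng, (n_heads, 2 * f_out)),
            leaky_slope=leaky_slope,
            concat=concat,
        )


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Boolean N x N reachability mask; the diagonal is always attended."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool).copy()
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("mask must be square")
        np.fill_diagonal(m, True)
        object.__setattr__(self, "mask", m)

    @classmethod
    def full(cls, n: int) -> "NeighborhoodSpec":
        return cls(np.ones((n, n), dtype=bool))

    @classmethod
    def from_adjacency(cls, w0: np.ndarray) -> "NeighborhoodSpec":
        return cls(np.asarray(w0) > 0)


# ---------------------------------------------------------------------------
# Single-instance functional API (reference surface; N x F inputs)


def attention_scores(
    h: np.ndarray,
    params: GATLayerParams,
    head: int,
    mask: NeighborhoodSpec | None = None,
) -> np.ndarray:
    """Pairwise attention logits e_ij for one head.

    Returns an N x N matrix with ``LeakyReLU(a^T [Wh_i || Wh_j])`` on
    neighborhood pairs and the masked sentinel elsewhere.
    """
    h = np.asarray(h, dtype=float)
    if not np.all(np.isfinite(h)):
        raise ValueError("node features must be finite")
    if not (0 <= head < params.n_heads):
        raise IndexError(f"head {head} out of range (K={params.n_heads})")
    z = h @ params.W_heads[head].T  # (N, F')
    fp = params.f_out
    a_src, a_dst = params.a_heads[head, :fp], params.a_heads[head, fp:]
    s = (z @ a_src)[:, None] + (z @ a_dst)[None, :]
    e = _leaky(s, params.leaky_slope)
    if mask is not None:
        e = np.where(mask.mask, e, MASK_SENTINEL)
    return e


def normalize_attention(e: np.ndarray, mask: NeighborhoodSpec) -> np.ndarray:
    """Row-wise softmax over each node's neighborhood; masked entries 0."""
    e = np.asarray(e, dtype=float)
    m = mask.mask
    if not m.any(axis=1).all():
        raise ValueError("every node needs at least one neighbor")
    logits = np.where(m, e, -np.inf)
    logits = logits - logits.max(axis=1, keepdims=True)
    ex = np.exp(logits)
    return ex / ex.sum(axis=1, keepdims=True)


def gat_head_forward(
    h: np.ndarray, alpha: np.ndarray, W: np.ndarray, activation: str = "elu"
) -> np.ndarray:
    """Aggregate one head: ``h'_i = act(sum_j alpha_ij W h_j)``."""
    h, alpha, W = (np.asarray(x, dtype=float) for x in (h, alpha, W))
    if alpha.shape[0] != alpha.shape[1] or alpha.shape[0] != h.shape[0]:
        raise ValueError("alpha must be N x N matching h")
    if W.shape[1] != h.shape[1]:
        raise ValueError("W columns must match feature dimension")
    act, _ = _ACTIVATIONS[activation]
    return act(alpha @ (h @ W.T))


def multi_head_forward(
    h: np.ndarray,
    params: GATLayerParams,
    mask: NeighborhoodSpec | None = None,
    activation: str = "elu",
) -> np.ndarray:
    """Static multi-head layer: per-head attention, concat (or average)."""
    h = np.asarray(h, dtype=float)
    if mask is None:
        mask = NeighborhoodSpec.full(h.shape[0])
    outs = []
    for k in range(params.n_heads):
        e = attention_scores(h, params, k, mask)
        alpha = normalize_attention(e, mask)
        outs.append(gat_head_forward(h, alpha, params.W_heads[k], activation))
    return (
        np.concatenate(outs, axis=1) if params.concat else np.mean(outs, axis=0)
    )


def dynamic_update(
    state: AdjacencyState, e: np.ndarray, training: bool = True
) -> AdjacencyState:
    """Momentum blend of the adjacency buffer toward fresh scores.

    ``w <- beta*w + (1-beta)*e`` elementwise on neighborhood pairs. A call
    in evaluation mode (or on a non-trainable state) is a warned no-op.
    """
    e = np.asarray(e, dtype=float)
    if e.shape != state.w.shape:
        raise ValueError("score matrix shape must match adjacency buffer")
    if not training or not state.trainable:
        warnings.warn("dynamic_update outside training is a no-op", stacklevel=2)
        return state
    m = state.mask()
    state.w[m] = state.beta * state.w[m] + (1 - state.beta) * e[m]
    return state


def dgat_layer_forward(
    h: np.ndarray,
    params: GATLayerParams,
    state: AdjacencyState,
    mask: NeighborhoodSpec | None = None,
    training: bool = False,
    activation: str = "elu",
) -> tuple[np.ndarray, AdjacencyState]:
    """One dynamic layer pass on a single N x F instance.

    Computes fresh scores per head, momentum-updates the buffer (training
    mode only), softmaxes the updated weights into attention coefficients,
    and aggregates per head with concatenation.
    """
    h = np.asarray(h, dtype=float)
    if mask is None:
        mask = NeighborhoodSpec.from_adjacency(state.w0)
    e_heads = [
        attention_scores(h, params, k, mask=None) for k in range(params.n_heads)
    ]
    b = state.beta
    # Each head blends its own fresh scores with the shared prior buffer,
    # so heads keep distinct attention; the buffer then absorbs the
    # head-averaged scores through the same momentum rule.
    d_heads = [b * state.w + (1 - b) * e for e in e_heads]
    if training and state.trainable:
        dynamic_update(state, np.mean(e_heads, axis=0), training=True)
    outs = []
    for k, d in enumerate(d_heads):
        alpha = normalize_attention(np.where(mask.mask, d, MASK_SENTINEL), mask)
        outs.append(gat_head_forward(h, alpha, params.W_heads[k], activation))
    out = np.concatenate(outs, axis=1) if params.concat else np.mean(outs, axis=0)
    return out, state


# ---------------------------------------------------------------------------
# Batched layer with analytic backward pass (used by the classifier)


class DGATLayer:
    """Batched dynamic graph-attention layer over (S, N, F) feature stacks.

    One adjacency buffer (``state``) is shared by all samples of a batch:
    each sample's attention logits are ``beta*w + (1-beta)*e_s`` and, after
    a training pass, the buffer absorbs the batch- and head-averaged
    scores through the same momentum rule. ``beta=0`` gives a plain static
    GAT; ``beta=1`` with a frozen buffer gives fixed, input-independent
    attention (the static-adjacency ablation arm).
    """

    def __init__(
        self,
        params: GATLayerParams,
        state: AdjacencyState,
        activation: str = "elu",
        attn_dropout: float = 0.0,
        per_head_adjacency: bool = False,
    ) -> None:
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation '{activation}'")
        self.params = params
        self.state = state
        self.activation = activation
        self.attn_dropout = float(attn_dropout)
        self.per_head = per_head_adjacency
        if per_head_adjacency and state.w.ndim == 2:
            state.w = np.repeat(state.w[None], params.n_heads, axis=0)
        self.mask = NeighborhoodSpec.from_adjacency(state.w0)
        self._cache: dict | None = None

    # -- forward -----------------------------------------------------------

    def forward(
        self,
        h: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """(S, N, F) -> (S, N, out_dim); caches intermediates for backward."""
        p = self.params
        h = np.asarray(h, dtype=float)
        s_n, n, _ = h.shape
        m = self.mask.mask
        beta = self.state.beta

        z = np.einsum("snf,kgf->ksng", h, p.W_heads)  # (K, S, N, F')
        fp = p.f_out
        a_src, a_dst = p.a_heads[:, :fp], p.a_heads[:, fp:]
        f = np.einsum("ksng,kg->ksn", z, a_src)
        g = np.einsum("ksng,kg->ksn", z, a_dst)
        s_logits = f[:, :, :, None] + g[:, :, None, :]  # (K, S, N, N)
        e = _leaky(s_logits, p.leaky_slope)

        w = self.state.w if self.per_head else self.state.w[None]
        d = beta * w[:, None] + (1 - beta) * e  # (K, S, N, N)
        d = np.where(m, d, MASK_SENTINEL)
        d_shift = d - d.max(axis=-1, keepdims=True)
        ex = np.exp(d_shift) * m
        alpha = ex / ex.sum(axis=-1, keepdims=True)

        if training and self.attn_dropout > 0:
            if rng is None:
                rng = np.random.default_rng()
            keep = 1.0 - self.attn_dropout
            drop = (rng.random(alpha.shape) < keep) / keep
        else:
            drop = None
        alpha_d = alpha if drop is None else alpha * drop

        u = np.einsum("ksnm,ksmg->ksng", alpha_d, z)
        act, act_grad = _ACTIVATIONS[self.activation]
        out_heads = act(u)  # (K, S, N, F')
        if p.concat:
            out = np.moveaxis(out_heads, 0, 2).reshape(s_n, n, p.n_heads * fp)
        else:
            out = out_heads.mean(axis=0)

        if training and self.state.trainable and beta < 1.0:
            upd = e.mean(axis=1) if self.per_head else e.mean(axis=(0, 1))
            wm = self.state.w
            if self.per_head:
                mm = np.broadcast_to(m, wm.shape)
            else:
                mm = m
            wm[mm] = beta * wm[mm] + (1 - beta) * upd[mm]

        self._cache = dict(
            h=h, z=z, s=s_logits, alpha=alpha, alpha_d=alpha_d, drop=drop, u=u,
            act_grad=act_grad(u), beta=beta,
        )
        return out

    # -- backward ----------------------------------------------------------

    def backward(self, d_out: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Gradients of a scalar loss through the cached forward pass.

        Returns ``(d_h, grads)`` where grads has ``"W"`` (K, F', F), ``"a"``
        (K, 2F') and ``"w"`` — the gradient with respect to the adjacency
        buffer as it entered the pass (diagnostic; the buffer itself is
        trained by the momentum rule, not by gradient descent).
        """
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        c = self._cache
        p = self.params
        h, z, alpha, alpha_d = c["h"], c["z"], c["alpha"], c["alpha_d"]
        s_n, n, _ = h.shape
        fp = p.f_out
        m = self.mask.mask
        beta = c["beta"]

        if p.concat:
            d_heads = np.moveaxis(
                d_out.reshape(s_n, n, p.n_heads, fp), 2, 0
            )  # (K, S, N, F')
        else:
            d_heads = np.repeat(d_out[None], p.n_heads, axis=0) / p.n_heads

        du = d_heads * c["act_grad"]
        d_alpha_d = np.einsum("ksng,ksmg->ksnm", du, z)
        dz = np.einsum("ksnm,ksng->ksmg", alpha_d, du)  # aggregation path
        d_alpha = d_alpha_d if c["drop"] is None else d_alpha_d * c["drop"]
        # softmax rows: dd = alpha * (d_alpha - <d_alpha, alpha>_row)
        inner = (d_alpha * alpha).sum(axis=-1, keepdims=True)
        dd = alpha * (d_alpha - inner)
        dd = np.where(m, dd, 0.0)
        de = (1 - beta) * dd
        dw = beta * dd.sum(axis=1)  # per head, summed over batch
        if not self.per_head:
            dw = dw.sum(axis=0)

        ds = de * _leaky_grad(c["s"], p.leaky_slope)
        df = ds.sum(axis=-1)  # (K, S, N)
        dg = ds.sum(axis=-2)
        a_src, a_dst = p.a_heads[:, :fp], p.a_heads[:, fp:]
        dz += df[..., None] * a_src[:, None, None, :]
        dz += dg[..., None] * a_dst[:, None, None, :]

        da_src = np.einsum("ksng,ksn->kg", z, df)
        da_dst = np.einsum("ksng,ksn->kg", z, dg)
        d_a = np.concatenate([da_src, da_dst], axis=1)
        d_w_heads = np.einsum("ksng,snf->kgf", dz, h)
        d_h = np.einsum("ksng,kgf->snf", dz, p.W_heads)
        return d_h, {"W": d_w_heads, "a": d_a, "w": dw}
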