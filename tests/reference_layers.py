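"""Scalar-loop reference implementation of the attention layers.

Deliberately naive: explicit Python loops and ``math`` scalars, no shared
code with the package's vectorized layers. Used as an independent oracle
on tiny graphs.
"""

import math

import numpy as np


def _leaky(x: float, slope: float) -> float:
    return x if x > 0 else slope * x


def _elu(x: float) -> float:
    return x if x > 0 else math.exp(x) - 1.0


def _act(name: str):
    return {"elu": _elu, "identity": lambda v: v}[name]


def reference_scores(h, W, a, slope=0.2):
    """e_ij = LeakyReLU(a^T [W h_i || W h_j]), element by element."""
    n = len(h)
    fp = W.shape[0]
    z = [[sum(W[g][f] * h[i][f] for f in range(W.shape[1])) for g in range(fp)] for i in range(n)]
    e = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            concat = z[i] + z[j]
            e[i, j] = _leaky(sum(a[t] * concat[t] for t in range(2 * fp)), slope)
    return e


def reference_softmax_rows(scores, mask):
    n = scores.shape[0]
    alpha = np.zeros((n, n))
    for i in range(n):
        idx = [j for j in range(n) if mask[i, j]]
        mx = max(scores[i, j] for j in idx)
        tot = sum(math.exp(scores[i, j] - mx) for j in idx)
        for j in idx:
            alpha[i, j] = math.exp(scores[i, j] - mx) / tot
    return alpha


def reference_aggregate(h, alpha, W, activation="elu"):
    n = len(h)
    fp, f = W.shape
    act = _act(activation)
    out = np.zeros((n, fp))
    for i in range(n):
        for g in range(fp):
            acc = 0.0
            for j in range(n):
                whj = sum(W[g][t] * h[j][t] for t in range(f))
                acc += alpha[i, j] * whj
            out[i, g] = act(acc)
    return out


def reference_static_multihead(h, W_heads, a_heads, mask, slope=0.2, activation="elu"):
    """Static multi-head layer: per-head score/softmax/aggregate, concat."""
    outs = []
    for k in range(W_heads.shape[0]):
        e = reference_scores(h, W_heads[k], a_heads[k], slope)
        masked = np.where(mask, e, -1e9)
        alpha = reference_softmax_rows(masked, mask)
        outs.append(reference_aggregate(h, alpha, W_heads[k], activation))
    return np.concatenate(outs, axis=1)


def reference_dynamic_layer(
    h, W_heads, a_heads, w, beta, mask, slope=0.2, activation="elu", update=True
):
    """Dynamic layer on one instance: score, momentum blend, softmax, aggregate.

    Returns (output, new_w). With ``update`` the buffer absorbs the
    head-averaged scores through the momentum rule on masked pairs.
    """
    k_heads = W_heads.shape[0]
    e_all = [reference_scores(h, W_heads[k], a_heads[k], slope) for k in range(k_heads)]
    n = w.shape[0]
    new_w = w.copy()
    if update:
        e_mean = sum(e_all) / k_heads
        for i in range(n):
            for j in range(n):
                if mask[i, j]:
                    new_w[i, j] = beta * w[i, j] + (1 - beta) * e_mean[i, j]
    outs = []
    for k in range(k_heads):
        d = beta * w + (1 - beta) * e_all[k]  # per-head blend with prior buffer
        masked = np.where(mask, d, -1e9)
        alpha = reference_softmax_rows(masked, mask)
        outs.append(reference_aggregate(h, alpha, W_heads[k], activation))
    return np.concatenate(outs, axis=1), new_w
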