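"""The dynamic graph-attention emotion classifier.

The network treats each electrode as a graph node whose feature vector is
its per-band differential entropy. A stack of dynamic graph-attention
layers (see :mod:`dgat.layers`) refines the node features while a
momentum-updated adjacency buffer learns inter-channel structure; the node
features are then flattened and passed through a fully connected layer for
dimensionality reduction and a linear softmax classifier. Training
minimizes cross-entropy plus an L2 penalty with Adam (learning rate 1e-3,
batch size 64 by default; adjacency momentum beta = 0.5).

The public surface follows the Model/Results convention: build a
:class:`DGATClassifier` from a feature tensor, call :meth:`~DGATClassifier.fit`,
and get a :class:`DGATResults` carrying the trained parameters, training
history, evaluation helpers and a ``summary()`` table.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .graph import AdjacencyState, adjacency_for_montage, make_adjacency_state
from .layers import DGATLayer, GATLayerParams
from .montage import DEFeatureTensor, Montage

__all__ = [
    "ModelConfig",
    "DGATNetwork",
    "DGATClassifier",
    "DGATResults",
    "EvalReport",
    "build_model",
    "loss",
    "cross_entropy",
    "train",
    "evaluate",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the classifier.

    ``f_out`` and ``n_heads`` may be single values (shared by all layers)
    or per-layer sequences of length ``n_layers``. ``beta`` is the
    adjacency momentum; ``beta=1`` with ``adjacency_trainable=False``
    freezes attention to the Gaussian-kernel graph (the static ablation
    arm), ``beta=0`` is a plain static GAT.
    """

    n_layers: int = 1
    f_out: int | tuple[int, ...] = 8
    n_heads: int | tuple[int, ...] = 3
    classifier_hidden: int = 32
    n_classes: int = 3
    beta: float = 0.5
    adjacency_trainable: bool = True
    per_head_adjacency: bool = False
    l2_lambda: float = 1e-4
    dropout: float = 0.0
    standardize: bool = True
    leaky_slope: float = 0.2
    activation: str = "elu"
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 300
    patience: int = 30
    min_delta: float = 1e-4
    theta: float | None = None  # Gaussian kernel width; None = mean distance
    tau: float = math.inf  # connection radius; inf = fully connected
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if not (0 <= self.beta <= 1):
            raise ValueError("beta must lie in [0, 1]")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")

    def per_layer(self, value) -> tuple[int, ...]:
        if np.isscalar(value):
            return tuple(int(value) for _ in range(self.n_layers))
        value = tuple(int(v) for v in value)
        if len(value) != self.n_layers:
            raise ValueError("per-layer setting length must equal n_layers")
        return value


def _relu(x):
    return np.maximum(x, 0.0)


class DGATNetwork:
    """Parameter container + forward/backward for the full architecture."""

    def __init__(self, config: ModelConfig, montage: Montage, n_bands: int) -> None:
        self.config = config
        self.montage = montage
        self.n_bands = n_bands
        rng = np.random.default_rng(config.seed)
        n = montage.n_channels
        w0 = adjacency_for_montage(montage, config.theta, config.tau)

        f_outs = config.per_layer(config.f_out)
        heads = config.per_layer(config.n_heads)
        self.layers: list[DGATLayer] = []
        f_in = n_bands
        for f_o, k in zip(f_outs, heads):
            params = GATLayerParams.init(
                rng, k, f_in, f_o, leaky_slope=config.leaky_slope
            )
            state = make_adjacency_state(
                w0, beta=config.beta, trainable=config.adjacency_trainable
            )
            self.layers.append(
                DGATLayer(
                    params,
                    state,
                    activation=config.activation,
                    attn_dropout=config.dropout,
                    per_head_adjacency=config.per_head_adjacency,
                )
            )
            f_in = k * f_o
        self.flat_dim = n * f_in
        lim1 = math.sqrt(6.0 / (self.flat_dim + config.classifier_hidden))
        lim2 = math.sqrt(6.0 / (config.classifier_hidden + config.n_classes))
        self.fc1_w = rng.uniform(-lim1, lim1, (config.classifier_hidden, self.flat_dim))
        self.fc1_b = np.zeros(config.classifier_hidden)
        self.fc2_w = rng.uniform(-lim2, lim2, (config.n_classes, config.classifier_hidden))
        self.fc2_b = np.zeros(config.n_classes)
        self._cache: dict | None = None

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        p: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            p[f"layer{i}.W"] = layer.params.W_heads
            p[f"layer{i}.a"] = layer.params.a_heads
        p["fc1_w"], p["fc1_b"] = self.fc1_w, self.fc1_b
        p["fc2_w"], p["fc2_b"] = self.fc2_w, self.fc2_b
        return p

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            layer.params.W_heads = np.array(params[f"layer{i}.W"], dtype=float)
            layer.params.a_heads = np.array(params[f"layer{i}.a"], dtype=float)
        self.fc1_w = np.array(params["fc1_w"], dtype=float)
        self.fc1_b = np.array(params["fc1_b"], dtype=float)
        self.fc2_w = np.array(params["fc2_w"], dtype=float)
        self.fc2_b = np.array(params["fc2_b"], dtype=float)

    def squared_param_norm(self) -> float:
        return float(sum(np.sum(v**2) for v in self.parameters().values()))

    # -- forward / backward -------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """(S, N, B) feature stacks -> (S, n_classes) logits."""
        x = np.asarray(x, dtype=float)
        s = x.shape[0]
        drop_in = None
        if training and self.config.dropout > 0 and rng is not None:
            keep = 1 - self.config.dropout
            drop_in = (rng.random(x.shape) < keep) / keep
            x = x * drop_in
        h = x
        for layer in self.layers:
            h = layer.forward(h, training=training, rng=rng)
        flat = h.reshape(s, -1)
        pre1 = flat @ self.fc1_w.T + self.fc1_b
        hid = _relu(pre1)
        logits = hid @ self.fc2_w.T + self.fc2_b
        self._cache = dict(drop_in=drop_in, flat=flat, pre1=pre1, hid=hid, h_shape=h.shape)
        return logits

    def backward(self, d_logits: np.ndarray) -> dict[str, np.ndarray]:
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        c = self._cache
        grads: dict[str, np.ndarray] = {}
        grads["fc2_w"] = d_logits.T @ c["hid"]
        grads["fc2_b"] = d_logits.sum(axis=0)
        d_hid = d_logits @ self.fc2_w
        d_pre1 = d_hid * (c["pre1"] > 0)
        grads["fc1_w"] = d_pre1.T @ c["flat"]
        grads["fc1_b"] = d_pre1.sum(axis=0)
        d_h = (d_pre1 @ self.fc1_w).reshape(c["h_shape"])
        for i in reversed(range(len(self.layers))):
            d_h, g = self.layers[i].backward(d_h)
            grads[f"layer{i}.W"] = g["W"]
            grads[f"layer{i}.a"] = g["a"]
        if c["drop_in"] is not None:
            d_h = d_h * c["drop_in"]
        return grads

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward(x, training=False), axis=1)

    def reset_adjacency(self) -> None:
        for layer in self.layers:
            layer.state.reset()
            if layer.per_head and layer.state.w.ndim == 2:
                layer.state.w = np.repeat(
                    layer.state.w[None], layer.params.n_heads, axis=0
                )


def build_model(config: ModelConfig, montage: Montage, n_bands: int) -> DGATNetwork:
    """Construct the untrained network; deterministic given ``config.seed``."""
    return DGATNetwork(config, montage, n_bands)


# ---------------------------------------------------------------------------
# Loss


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient with respect to the logits."""
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels, dtype=int)
    s, c = logits.shape
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError(f"labels must lie in [0, {c})")
    shift = logits - logits.max(axis=1, keepdims=True)
    logz = np.log(np.exp(shift).sum(axis=1, keepdims=True))
    logp = shift - logz
    ce = -float(logp[np.arange(s), labels].mean())
    probs = np.exp(logp)
    d_logits = probs
    d_logits[np.arange(s), labels] -= 1.0
    return ce, d_logits / s


def loss(
    logits: np.ndarray,
    labels: np.ndarray,
    params: dict[str, np.ndarray] | list[np.ndarray] | None = None,
    l2_lambda: float = 0.0,
) -> float:
    """Mean cross-entropy plus ``l2_lambda * sum ||params||^2``."""
    ce, _ = cross_entropy(logits, labels)
    if l2_lambda and params is not None:
        vals = params.values() if isinstance(params, dict) else params
        ce += l2_lambda * float(sum(np.sum(np.asarray(v) ** 2) for v in vals))
    return ce


# ---------------------------------------------------------------------------
# Adam


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Training / evaluation primitives


@dataclass
class EvalReport:
    """Accuracy, confusion counts, and per-fold / per-subject breakdown."""

    accuracy: float
    confusion: np.ndarray  # (n_classes, n_classes), rows = true class
    per_unit: dict[str, float] = field(default_factory=dict)
    std: float = float("nan")

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion)
        if np.any(self.confusion < 0):
            raise ValueError("confusion counts must be nonnegative")

    @classmethod
    def from_confusion(
        cls, confusion: np.ndarray, per_unit: dict[str, float] | None = None
    ) -> "EvalReport":
        confusion = np.asarray(confusion)
        total = confusion.sum()
        acc = float(np.trace(confusion) / total) if total else float("nan")
        per_unit = per_unit or {}
        std = float(np.std(list(per_unit.values()))) if per_unit else float("nan")
        return cls(accuracy=acc, confusion=confusion, per_unit=per_unit, std=std)

    def summary(self) -> str:
        lines = [
            f"accuracy: {self.accuracy:.4f}"
            + (f" +/- {self.std:.4f}" if not math.isnan(self.std) else ""),
            "confusion (rows = true):",
        ]
        for row in self.confusion:
            lines.append("  " + " ".join(f"{int(v):6d}" for v in row))
        for name, acc in self.per_unit.items():
            lines.append(f"  {name}: {acc:.4f}")
        return "\n".join(lines)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def train(
    net: DGATNetwork,
    x: np.ndarray,
    y: np.ndarray,
    config: ModelConfig | None = None,
) -> list[dict[str, float]]:
    """Optimize the network in place; returns per-epoch history.

    Mini-batch Adam on cross-entropy + L2, with early stopping when the
    epoch training loss has not improved by ``min_delta`` for ``patience``
    epochs. Fully reproducible given ``config.seed``. Raises on divergence.
    """
    cfg = config or net.config
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if cfg.epochs == 0:
        return []
    rng = np.random.default_rng(cfg.seed + 1)  # training stream, distinct from init
    params = net.parameters()
    opt = Adam(params, cfg.lr)
    history: list[dict[str, float]] = []
    best = math.inf
    stall = 0
    n = len(y)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        ep_correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = net.forward(x[idx], training=True, rng=rng)
            ce, d_logits = cross_entropy(logits, y[idx])
            total = ce + cfg.l2_lambda * net.squared_param_norm()
            if not math.isfinite(total):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (loss={total}); "
                    "reduce the learning rate or check the input scale"
                )
            grads = net.backward(d_logits)
            if cfg.l2_lambda:
                for k, p in params.items():
                    grads[k] = grads[k] + 2 * cfg.l2_lambda * p
            opt.step(params, grads)
            ep_loss += total * len(idx)
            ep_correct += int((np.argmax(logits, axis=1) == y[idx]).sum())
        ep_loss /= n
        history.append({"epoch": epoch, "loss": ep_loss, "accuracy": ep_correct / n})
        if ep_loss < best - cfg.min_delta:
            best = ep_loss
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    return history


def evaluate(net: DGATNetwork, x: np.ndarray, y: np.ndarray) -> EvalReport:
    """Accuracy and confusion counts with frozen adjacency buffers."""
    y = np.asarray(y, dtype=int)
    if len(y) == 0:
        raise ValueError("cannot evaluate on an empty set")
    pred = net.predict(np.asarray(x, dtype=float))
    return EvalReport.from_confusion(_confusion(y, pred, net.config.n_classes))


# ---------------------------------------------------------------------------
# Model / Results surface


class DGATClassifier:
    """Emotion classifier over a differential-entropy feature tensor.

    Parameters
    ----------
    features
        A :class:`~dgat.montage.DEFeatureTensor` (windows x channels x
        bands with per-window labels).
    config
        A :class:`ModelConfig`; keyword overrides may be passed instead
        (``DGATClassifier(t, n_heads=3, beta=0.5)``).
    """

    def __init__(
        self,
        features: DEFeatureTensor,
        config: ModelConfig | None = None,
        **overrides,
    ) -> None:
        if config is None:
            config = ModelConfig(
                n_classes=int(np.max(features.labels)) + 1 if features.n_windows else 2
            )
        if overrides:
            config = replace(config, **overrides)
        self.features = features
        self.config = config
        self.montage = features.montage

    @classmethod
    def from_features(cls, features: DEFeatureTensor, **kwargs) -> "DGATClassifier":
        return cls(features, **kwargs)

    def fit(self, train_idx: np.ndarray | None = None) -> "DGATResults":
        """Train on all windows (or the given subset) and return results.

        With ``config.standardize`` (default), features are z-scored per
        (channel, band) using training-split statistics; the statistics
        travel with the results and are applied at prediction time.
        """
        t = self.features
        x, y = t.values, t.labels
        if train_idx is not None:
            x, y = x[train_idx], y[train_idx]
        if self.config.standardize and len(y):
            mu = x.mean(axis=0)
            sd = x.std(axis=0)
            sd[sd == 0] = 1.0
        else:
            mu = np.zeros(x.shape[1:])
            sd = np.ones(x.shape[1:])
        net = build_model(self.config, self.montage, t.n_bands)
        history = train(net, (x - mu) / sd, y, self.config)
        return DGATResults(self, net, history, mu=mu, sd=sd)


class DGATResults:
    """Fitted classifier: trained parameters, history, and diagnostics."""

    def __init__(
        self,
        model: DGATClassifier,
        net: DGATNetwork,
        history: list[dict[str, float]],
        mu: np.ndarray | None = None,
        sd: np.ndarray | None = None,
    ) -> None:
        self.model = model
        self.net = net
        self.history = history
        self.config = model.config
        shape = (model.montage.n_channels, model.features.n_bands)
        self.mu = np.zeros(shape) if mu is None else mu
        self.sd = np.ones(shape) if sd is None else sd

    def _prep(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mu) / self.sd

    # -- prediction / evaluation -------------------------------------------

    def predict(self, x: np.ndarray | DEFeatureTensor) -> np.ndarray:
        if isinstance(x, DEFeatureTensor):
            x = x.values
        return self.net.predict(self._prep(x))

    def evaluate(
        self, x: np.ndarray | DEFeatureTensor, y: np.ndarray | None = None
    ) -> EvalReport:
        if isinstance(x, DEFeatureTensor):
            x, y = x.values, x.labels
        if y is None:
            raise ValueError("labels required when passing a raw array")
        return evaluate(self.net, self._prep(x), np.asarray(y, dtype=int))

    # -- learned structure ---------------------------------------------------

    def adjacency(self, layer: int = 0) -> np.ndarray:
        """The momentum-updated adjacency buffer of the given layer."""
        return self.net.layers[layer].state.w.copy()

    def attention(self, x: np.ndarray | DEFeatureTensor, layer: int = 0) -> np.ndarray:
        """Per-sample post-update attention (S, N, N), head-averaged."""
        if isinstance(x, DEFeatureTensor):
            x = x.values
        h = self._prep(x)
        for i, lay in enumerate(self.net.layers):
            out = lay.forward(h, training=False)
            if i == layer:
                return lay._cache["alpha"].mean(axis=0)  # average heads
            h = out
        raise IndexError(f"layer {layer} out of range")

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        cfg = self.config
        head = [
            "Dynamic graph attention classifier",
            "===================================",
            f"nodes (channels):    {self.model.montage.n_channels}",
            f"node features:       {self.model.features.n_bands} bands (DE, nats)",
            f"layers:              {cfg.n_layers} "
            f"(F'={cfg.per_layer(cfg.f_out)}, heads={cfg.per_layer(cfg.n_heads)})",
            f"classes:             {cfg.n_classes}",
            f"adjacency momentum:  beta={cfg.beta}"
            + ("" if cfg.adjacency_trainable else " (frozen)"),
            f"optimizer:           Adam lr={cfg.lr}, batch={cfg.batch_size}, "
            f"l2={cfg.l2_lambda}",
        ]
        if self.history:
            last = self.history[-1]
            head.append(
                f"training:            {len(self.history)} epochs, "
                f"final loss {last['loss']:.4f}, "
                f"final accuracy {last['accuracy']:.4f}"
            )
        else:
            head.append("training:            not trained (0 epochs)")
        return "\n".join(head)

    def history_csv(self, path) -> None:
        """Per-epoch training metrics (loss, accuracy) as CSV."""
        import pandas as pd

        pd.DataFrame(self.history).to_csv(path, index=False)

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint: parameters, adjacency buffers, config, history."""
        arrays = {k: v for k, v in self.net.parameters().items()}
        for i, lay in enumerate(self.net.layers):
            arrays[f"state{i}.w"] = lay.state.w
            arrays[f"state{i}.w0"] = lay.state.w0
        meta = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.config).items()
            },
            "history": self.history,
            "n_bands": self.model.features.n_bands,
            "montage_labels": list(self.model.montage.channel_labels),
        }
        arrays["montage_positions"] = self.model.montage.positions
        arrays["standardize_mu"] = self.mu
        arrays["standardize_sd"] = self.sd
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    @staticmethod
    def load(path, features: DEFeatureTensor) -> "DGATResults":
        """Restore a checkpoint against a compatible feature tensor."""
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        cfg_dict = meta["config"]
        for key in ("f_out", "n_heads"):
            if isinstance(cfg_dict[key], list):
                cfg_dict[key] = tuple(cfg_dict[key])
        cfg_dict["tau"] = float(cfg_dict["tau"]) if cfg_dict["tau"] is not None else math.inf
        config = ModelConfig(**cfg_dict)
        model = DGATClassifier(features, config)
        net = build_model(config, features.montage, meta["n_bands"])
        net.set_parameters({k: data[k] for k in net.parameters()})
        for i, lay in enumerate(net.layers):
            lay.state.w = np.array(data[f"state{i}.w"])
        return DGATResults(
            model,
            net,
            meta["history"],
            mu=np.array(data["standardize_mu"]),
            sd=np.array(data["standardize_sd"]),
        )
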