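"""Denoising auto-encoder layers, greedy layer-wise pretraining, and
supervised fine-tuning for binary splice-site classification.

The model is a stack of auto-encoder layers. Each layer encodes
``h = S_f(W x + b_h)`` and reconstructs ``x* = S_g(W' h + b_x)`` with
independent (untied) decoder weights. Pretraining minimises the denoising
reconstruction cost: the input is corrupted by masking a fixed fraction of
positions to zero, the reconstruction is compared against the *clean*
input, and the empirical mean loss over the training set is driven down by
plain mini-batch SGD. After pretraining layer by layer (layer k trains on
the hidden codes of layers 1..k-1), a single sigmoid output unit is added
and the whole stack is fine-tuned on binary cross-entropy, keeping the
parameters that score best on a held-out validation subset.

Everything is seeded and deterministic: the same data, configuration and
seed reproduce bitwise-identical parameters and predictions.
"""

from __future__ import annotations

import copy
import json
import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "AELayerParams",
    "TrainConfig",
    "StackedNetwork",
    "ae_forward",
    "corrupt",
    "ae_cost",
    "cost_update",
    "init_layer",
    "pretrain_layer",
    "build_network",
    "pretrain_stack",
    "finetune",
    "predict_proba",
    "classify",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# Parameters and configuration
# ---------------------------------------------------------------------------

_ACTIVATIONS = ("sigmoid", "linear")


@dataclass
class AELayerParams:
    """One auto-encoder layer: encoder W/b_h, decoder W'/b_x, activations."""

    W: np.ndarray          # (d_hidden, d_in)
    W_prime: np.ndarray    # (d_in, d_hidden)
    b_h: np.ndarray        # (d_hidden,)
    b_x: np.ndarray        # (d_in,)
    S_f: str = "sigmoid"
    S_g: str = "sigmoid"

    def __post_init__(self) -> None:
        d_h, d_in = self.W.shape
        if self.W_prime.shape != (d_in, d_h):
            raise ValueError(
                f"W_prime shape {self.W_prime.shape} != ({d_in}, {d_h})"
            )
        if self.b_h.shape != (d_h,) or self.b_x.shape != (d_in,):
            raise ValueError("bias shapes inconsistent with W")
        for a in (self.S_f, self.S_g):
            if a not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {a!r}")
        for arr in (self.W, self.W_prime, self.b_h, self.b_x):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite layer parameters")

    @property
    def d_in(self) -> int:
        return self.W.shape[1]

    @property
    def d_hidden(self) -> int:
        return self.W.shape[0]

    def copy(self) -> "AELayerParams":
        return AELayerParams(
            self.W.copy(), self.W_prime.copy(),
            self.b_h.copy(), self.b_x.copy(), self.S_f, self.S_g,
        )


@dataclass
class TrainConfig:
    """Hyper-parameters shared by pretraining and fine-tuning.

    ``corruption_fraction`` is the fraction of input positions masked to
    zero before encoding (denoising); the loss always compares against the
    clean input. ``loss`` selects squared error (default, any real inputs)
    or cross-entropy (inputs must lie in [0, 1]).
    """

    epochs: int = 15
    learning_rate: float = 0.1
    batch_size: int = 32
    corruption_fraction: float = 0.1
    loss: str = "squared_error"
    seed: int = 0
    validation_fraction: float = 0.1
    weight_decay: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.corruption_fraction <= 1.0:
            raise ValueError("corruption_fraction must be in [0, 1]")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.loss not in ("squared_error", "cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")


def default_finetune_config(seed: int = 0, **kw) -> TrainConfig:
    """Fine-tuning defaults: no input corruption, smaller batches, more
    epochs, and L2 weight decay — the supervised stage underfits badly
    with the pretraining step size and overfits without decay."""
    kw.setdefault("learning_rate", 0.2)
    kw.setdefault("corruption_fraction", 0.0)
    kw.setdefault("epochs", 60)
    kw.setdefault("batch_size", 16)
    kw.setdefault("weight_decay", 1e-3)
    return TrainConfig(seed=seed, **kw)


@dataclass
class StackedNetwork:
    """Ordered AE layers plus a single sigmoid output unit."""

    layers: list[AELayerParams]
    out_w: np.ndarray        # (d_last_hidden,)
    out_b: float
    threshold: float = 0.5
    scheme_name: str | None = None
    pretrain_traces: list[list[float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in zip(self.layers, self.layers[1:]):
            if b.d_in != a.d_hidden:
                raise ValueError("adjacent layer dimensions do not chain")
        if self.layers and self.out_w.shape != (self.layers[-1].d_hidden,):
            raise ValueError("output width does not match last hidden width")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")

    @property
    def d_input(self) -> int:
        return self.layers[0].d_in

    def copy(self) -> "StackedNetwork":
        return StackedNetwork(
            [l.copy() for l in self.layers],
            self.out_w.copy(), float(self.out_b), self.threshold,
            self.scheme_name, copy.deepcopy(self.pretrain_traces),
        )


# ---------------------------------------------------------------------------
# Activations and forward pass
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _act(z: np.ndarray, name: str) -> np.ndarray:
    return _sigmoid(z) if name == "sigmoid" else z


def _act_deriv(a: np.ndarray, name: str) -> np.ndarray:
    """Derivative expressed through the activation value ``a``."""
    return a * (1.0 - a) if name == "sigmoid" else np.ones_like(a)


def ae_forward(
    x: np.ndarray, params: AELayerParams
) -> tuple[np.ndarray, np.ndarray]:
    """One layer's encode/decode: returns ``(h, x_star)``.

    Accepts a single vector or a batch matrix (rows are samples).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != params.d_in:
        raise ValueError(f"input width {X.shape[1]} != layer d_in {params.d_in}")
    H = _act(X @ params.W.T + params.b_h, params.S_f)
    Xs = _act(H @ params.W_prime.T + params.b_x, params.S_g)
    if single:
        return H[0], Xs[0]
    return H, Xs


# ---------------------------------------------------------------------------
# Denoising corruption
# ---------------------------------------------------------------------------

def corrupt(
    x: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Mask exactly ``round(fraction * len(x))`` positions of ``x`` to zero.

    Positions are chosen uniformly without replacement; the input is not
    modified.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    k = int(round(fraction * n))
    out = x.copy()
    if k:
        idx = rng.choice(n, size=k, replace=False)
        out[..., idx] = 0.0
    return out


def _row_mask(
    row: np.ndarray, fraction: float, seed: int
) -> np.ndarray:
    """Deterministic per-row corruption mask keyed on the row's content.

    Duplicated rows receive identical masks, so duplicating a batch leaves
    the mean denoising cost unchanged.
    """
    n = row.shape[0]
    k = int(round(fraction * n))
    mask = np.ones(n)
    if k:
        row_seed = (seed * 1_000_003 + zlib.crc32(row.tobytes())) % (2**31)
        rng = np.random.default_rng(row_seed)
        mask[rng.choice(n, size=k, replace=False)] = 0.0
    return mask


def _batch_masks(
    batch: np.ndarray, config: TrainConfig, rng: np.random.Generator | None
) -> np.ndarray:
    frac = config.corruption_fraction
    if frac == 0.0:
        return np.ones_like(batch)
    if rng is None:
        return np.vstack([_row_mask(r, frac, config.seed) for r in batch])
    n, d = batch.shape
    k = int(round(frac * d))
    masks = np.ones((n, d))
    for i in range(n):
        masks[i, rng.choice(d, size=k, replace=False)] = 0.0
    return masks


# ---------------------------------------------------------------------------
# Cost and gradient
# ---------------------------------------------------------------------------

def _loss_terms(
    X: np.ndarray, Xs: np.ndarray, loss: str
) -> np.ndarray:
    if loss == "squared_error":
        return np.sum((X - Xs) ** 2, axis=1)
    if np.any(X < 0) or np.any(X > 1):
        raise ValueError("cross_entropy requires inputs in [0, 1]")
    eps = 1e-12
    Xc = np.clip(Xs, eps, 1 - eps)
    return -np.sum(X * np.log(Xc) + (1 - X) * np.log(1 - Xc), axis=1)


def ae_cost(
    batch: np.ndarray,
    params: AELayerParams,
    config: TrainConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Mean denoising reconstruction cost over the batch rows.

    Each row is corrupted (masked to zero at the configured fraction),
    passed through encode/decode, and compared against the clean row under
    the configured loss. With ``rng=None`` corruption masks are derived
    deterministically from each row's content and the config seed.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.size == 0:
        raise ValueError("empty batch")
    masks = _batch_masks(batch, config, rng)
    _, Xs = ae_forward(batch * masks, params)
    return float(np.mean(_loss_terms(batch, Xs, config.loss)))


def _cost_and_grads(
    params: AELayerParams,
    batch: np.ndarray,
    masks: np.ndarray,
    loss: str,
) -> tuple[float, dict[str, np.ndarray]]:
    """Cost plus analytic gradients for fixed corruption masks."""
    n = batch.shape[0]
    Xc = batch * masks
    A1 = Xc @ params.W.T + params.b_h
    H = _act(A1, params.S_f)
    A2 = H @ params.W_prime.T + params.b_x
    Xs = _act(A2, params.S_g)
    cost = float(np.mean(_loss_terms(batch, Xs, loss)))

    if loss == "squared_error":
        dXs = 2.0 * (Xs - batch) / n
        dA2 = dXs * _act_deriv(Xs, params.S_g)
    else:  # cross-entropy; sigmoid decoder cancels the derivative
        if params.S_g != "sigmoid":
            raise ValueError("cross_entropy requires a sigmoid decoder")
        dA2 = (Xs - batch) / n
    dWp = dA2.T @ H
    db_x = dA2.sum(axis=0)
    dH = dA2 @ params.W_prime
    dA1 = dH * _act_deriv(H, params.S_f)
    dW = dA1.T @ Xc
    db_h = dA1.sum(axis=0)
    grads = {"W": dW, "W_prime": dWp, "b_h": db_h, "b_x": db_x}
    return cost, grads


def cost_update(
    params: AELayerParams,
    batch: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator | None = None,
) -> AELayerParams:
    """One gradient-descent step on the denoising cost; params copied, not
    modified in place."""
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    masks = _batch_masks(batch, config, rng)
    _, grads = _cost_and_grads(params, batch, masks, config.loss)
    for g in grads.values():
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradient in cost update")
    lr = config.learning_rate
    return AELayerParams(
        params.W - lr * grads["W"],
        params.W_prime - lr * grads["W_prime"],
        params.b_h - lr * grads["b_h"],
        params.b_x - lr * grads["b_x"],
        params.S_f,
        params.S_g,
    )


# ---------------------------------------------------------------------------
# Initialisation and layer-wise pretraining
# ---------------------------------------------------------------------------

def init_layer(
    d_in: int,
    d_hidden: int,
    rng: np.random.Generator,
    *,
    S_f: str = "sigmoid",
    S_g: str = "sigmoid",
    tied: bool = False,
) -> AELayerParams:
    """Seeded uniform init in ±4·sqrt(6/(fan_in+fan_out)), zero biases."""
    if d_in < 1 or d_hidden < 1:
        raise ValueError("layer sizes must be >= 1")
    limit = 4.0 * np.sqrt(6.0 / (d_in + d_hidden))
    W = rng.uniform(-limit, limit, size=(d_hidden, d_in))
    W_prime = W.T.copy() if tied else rng.uniform(
        -limit, limit, size=(d_in, d_hidden)
    )
    return AELayerParams(
        W, W_prime, np.zeros(d_hidden), np.zeros(d_in), S_f, S_g
    )


def pretrain_layer(
    data: np.ndarray,
    d_hidden: int,
    config: TrainConfig,
    rng: np.random.Generator | None = None,
) -> tuple[AELayerParams, list[float]]:
    """Train one denoising AE layer on ``data`` by mini-batch SGD.

    Returns the trained parameters and the per-epoch mean-cost trace.
    ``epochs=0`` returns the seeded initialisation with an empty trace.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.size == 0:
        raise ValueError("empty training data")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    params = init_layer(data.shape[1], d_hidden, rng)
    trace: list[float] = []
    n = data.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_costs = []
        for start in range(0, n, config.batch_size):
            batch = data[order[start : start + config.batch_size]]
            masks = _batch_masks(batch, config, rng)
            cost, grads = _cost_and_grads(
                params, batch, masks, config.loss
            )
            for g in grads.values():
                if not np.all(np.isfinite(g)):
                    raise FloatingPointError("non-finite gradient")
            lr = config.learning_rate
            params = AELayerParams(
                params.W - lr * grads["W"],
                params.W_prime - lr * grads["W_prime"],
                params.b_h - lr * grads["b_h"],
                params.b_x - lr * grads["b_x"],
                params.S_f,
                params.S_g,
            )
            epoch_costs.append(cost)
        trace.append(float(np.mean(epoch_costs)))
    return params, trace


def default_hidden_sizes(d_input: int) -> list[int]:
    """Two hidden layers scaled to the input width (e.g. 90 -> [64, 32],
    15 -> [16, 8])."""
    if d_input >= 64:
        return [64, 32]
    return [16, 8]


def build_network(
    d_input: int,
    hidden_sizes: Sequence[int] | None = None,
    *,
    seed: int = 0,
    scheme_name: str | None = None,
) -> StackedNetwork:
    """Build an untrained stack of AE layers plus a sigmoid output unit."""
    if d_input < 1:
        raise ValueError("d_input must be >= 1")
    if hidden_sizes is None:
        hidden_sizes = default_hidden_sizes(d_input)
    hidden_sizes = list(hidden_sizes)
    if not hidden_sizes:
        raise ValueError("hidden_sizes must be non-empty")
    if any(h < 1 for h in hidden_sizes):
        raise ValueError("zero-size hidden layers not allowed")
    rng = np.random.default_rng(seed)
    layers = []
    d = d_input
    for h in hidden_sizes:
        layers.append(init_layer(d, h, rng))
        d = h
    limit = 4.0 * np.sqrt(6.0 / (d + 1))
    out_w = rng.uniform(-limit, limit, size=d)
    return StackedNetwork(layers, out_w, 0.0, scheme_name=scheme_name)


def _encode_through(
    X: np.ndarray, layers: Sequence[AELayerParams]
) -> np.ndarray:
    H = np.atleast_2d(np.asarray(X, dtype=float))
    for layer in layers:
        H = _act(H @ layer.W.T + layer.b_h, layer.S_f)
    return H


def pretrain_stack(
    network: StackedNetwork, data: np.ndarray, config: TrainConfig
) -> StackedNetwork:
    """Greedy layer-wise pretraining: layer k trains on the hidden codes of
    layers 1..k-1. The output unit is untouched. Layer k uses seed
    ``config.seed + k`` so a one-layer stack reduces to ``pretrain_layer``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[1] != network.d_input:
        raise ValueError(
            f"data width {data.shape[1]} != network input {network.d_input}"
        )
    net = network.copy()
    net.pretrain_traces = []
    H = data
    for k, layer in enumerate(net.layers):
        cfg = replace(config, seed=config.seed + k)
        trained, trace = pretrain_layer(H, layer.d_hidden, cfg)
        net.layers[k] = trained
        net.pretrain_traces.append(trace)
        H = _encode_through(H, [trained])
    return net


# ---------------------------------------------------------------------------
# Supervised fine-tuning
# ---------------------------------------------------------------------------

def _supervised_cost_grads(
    net: StackedNetwork, X: np.ndarray, y: np.ndarray
) -> tuple[float, list[dict], np.ndarray, float]:
    """Binary cross-entropy and gradients through encoders + output unit."""
    n = X.shape[0]
    acts = [X]
    H = X
    for layer in net.layers:
        H = _act(H @ layer.W.T + layer.b_h, layer.S_f)
        acts.append(H)
    z = H @ net.out_w + net.out_b
    p = _sigmoid(z)
    eps = 1e-12
    cost = float(
        -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    )
    dz = (p - y) / n
    d_out_w = acts[-1].T @ dz
    d_out_b = float(dz.sum())
    dH = np.outer(dz, net.out_w)
    layer_grads: list[dict] = [None] * len(net.layers)  # type: ignore
    for k in range(len(net.layers) - 1, -1, -1):
        layer = net.layers[k]
        dA = dH * _act_deriv(acts[k + 1], layer.S_f)
        layer_grads[k] = {"W": dA.T @ acts[k], "b_h": dA.sum(axis=0)}
        dH = dA @ layer.W
    return cost, layer_grads, d_out_w, d_out_b


def finetune(
    network: StackedNetwork,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
) -> StackedNetwork:
    """Supervised fine-tuning of the whole stack on binary cross-entropy.

    A seeded validation subset (``config.validation_fraction``) is held out
    and monitored each epoch; the best-validation parameters are returned.
    Decoder weights are frozen during fine-tuning (they only serve
    pretraining).
    """
    if config is None:
        config = default_finetune_config()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y lengths differ")
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("labels must be binary 0/1")
    if classes.size < 2:
        raise ValueError("need at least one sample of each class")
    net = network.copy()
    if config.epochs == 0:
        return net

    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    n_val = int(round(config.validation_fraction * n))
    order = rng.permutation(n)
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if tr_idx.size == 0:
        raise ValueError("validation fraction leaves no training data")
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    best = net.copy()
    best_val = np.inf
    lr = config.learning_rate
    wd = config.weight_decay
    for _ in range(config.epochs):
        perm = rng.permutation(Xtr.shape[0])
        for start in range(0, Xtr.shape[0], config.batch_size):
            idx = perm[start : start + config.batch_size]
            _, lgrads, d_out_w, d_out_b = _supervised_cost_grads(
                net, Xtr[idx], ytr[idx]
            )
            for layer, g in zip(net.layers, lgrads):
                layer.W -= lr * (g["W"] + wd * layer.W)
                layer.b_h -= lr * g["b_h"]
            net.out_w -= lr * (d_out_w + wd * net.out_w)
            net.out_b -= lr * d_out_b
        if n_val:
            val_cost, _, _, _ = _supervised_cost_grads(net, Xval, yval)
        else:
            val_cost, _, _, _ = _supervised_cost_grads(net, Xtr, ytr)
        if val_cost < best_val:
            best_val = val_cost
            best = net.copy()
    return best


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_proba(network: StackedNetwork, x: np.ndarray) -> np.ndarray | float:
    """Sigmoid output probability for one sample (float) or a batch
    (vector)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != network.d_input:
        raise ValueError(
            f"input width {X.shape[1]} != network input {network.d_input}"
        )
    H = _encode_through(X, network.layers)
    p = _sigmoid(H @ network.out_w + network.out_b)
    return float(p[0]) if single else p


def classify(network: StackedNetwork, x: np.ndarray) -> np.ndarray | int:
    """Hard call: 1 iff probability >= threshold (ties go positive)."""
    p = predict_proba(network, x)
    if np.isscalar(p):
        return int(p >= network.threshold)
    return (p >= network.threshold).astype(int)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(network: StackedNetwork, path: str) -> None:
    """Write the network to an ``.npz`` container (arrays + JSON metadata).

    Round-trip loading is bitwise-stable for predictions.
    """
    arrays: dict[str, np.ndarray] = {}
    meta = {
        "n_layers": len(network.layers),
        "activations": [[l.S_f, l.S_g] for l in network.layers],
        "threshold": network.threshold,
        "scheme_name": network.scheme_name,
        "out_b": float(network.out_b),
        "pretrain_traces": network.pretrain_traces,
    }
    for k, layer in enumerate(network.layers):
        arrays[f"W{k}"] = layer.W
        arrays[f"Wp{k}"] = layer.W_prime
        arrays[f"bh{k}"] = layer.b_h
        arrays[f"bx{k}"] = layer.b_x
    arrays["out_w"] = network.out_w
    arrays["meta"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path: str) -> StackedNetwork:
    """Load a network written by :func:`save_model`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        layers = []
        for k in range(meta["n_layers"]):
            S_f, S_g = meta["activations"][k]
            layers.append(
                AELayerParams(
                    data[f"W{k}"], data[f"Wp{k}"],
                    data[f"bh{k}"], data[f"bx{k}"], S_f, S_g,
                )
            )
        net = StackedNetwork(
            layers,
            data["out_w"],
            meta["out_b"],
            meta["threshold"],
            meta["scheme_name"],
            meta["pretrain_traces"],
        )
    return net
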