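"""Multi-layer perceptron: forward pass, cross-entropy training, input gradients.

The classifier is a four-layer MLP (hidden widths 1024, 256, 64, then 2
output neurons, one per class) over the flattened upper-triangle edge vector.
ReLU follows each hidden layer; the output layer feeds a softmax.  Training
is full-batch Adam on the mean cross-entropy — cohorts here are a few dozen
participants, so full batch is natural and removes batch-order
nondeterminism.  All forward, backward and update arithmetic is explicit
numpy; the input gradient used for saliency is therefore exact (and is
checked against central finite differences in the test suite).

Saliency gradient modes
-----------------------
``probability``  d p_c / d x    (default; the two classes' gradients are
                                exact negatives because p_0 + p_1 = 1)
``logit``        d z_c / d x
``margin``       d (z_c - z_{1-c}) / d x
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

DEFAULT_HIDDEN = (1024, 256, 64)
N_CLASSES = 2

GRADIENT_MODES = ("probability", "logit", "margin")

try:  # numba fuses the Adam update into one memory pass; numpy path is identical math
    from numba import njit as _njit

    @_njit(cache=True, fastmath=True)
    def _adam_apply(w, g, m, v, lr, beta1, beta2, corr1, corr2, eps):
        one = w.dtype.type(1.0)
        for idx in range(w.size):
            gi = g[idx]
            mi = beta1 * m[idx] + (one - beta1) * gi
            vi = beta2 * v[idx] + (one - beta2) * gi * gi
            m[idx] = mi
            v[idx] = vi
            w[idx] -= lr * (mi / corr1) / (np.sqrt(vi / corr2) + eps)

    def _adam_step(w, g, m, v, lr, beta1, beta2, corr1, corr2, eps):
        # scalars cast to the parameter dtype so the kernel vectorises cleanly
        t = w.dtype.type
        _adam_apply(w.reshape(-1), g.reshape(-1), m.reshape(-1), v.reshape(-1),
                    t(lr), t(beta1), t(beta2), t(corr1), t(corr2), t(eps))
except ImportError:  # pragma: no cover - numba is an optional accelerator
    def _adam_step(w, g, m, v, lr, beta1, beta2, corr1, corr2, eps):
        m *= beta1
        m += (1.0 - beta1) * g
        v *= beta2
        v += (1.0 - beta2) * np.square(g)
        w -= (lr * (m / corr1) / (np.sqrt(v / corr2) + eps)).astype(w.dtype)


@dataclass
class MLPParams:
    """Weights and biases of the four affine layers.

    ``weights[l]`` has shape ``(fan_in, fan_out)``; activations are computed
    as ``h @ W + b``.  ``dtype`` is float32 by default for training speed;
    float64 is available where strict gradient accuracy matters.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]

    @property
    def layer_widths(self) -> tuple[int, ...]:
        return tuple(w.shape[1] for w in self.weights)

    def copy(self) -> "MLPParams":
        return MLPParams([w.copy() for w in self.weights],
                         [b.copy() for b in self.biases])

    def validate(self) -> None:
        if len(self.weights) != len(self.biases):
            raise ValueError("weights/biases length mismatch")
        for l in range(1, self.n_layers):
            if self.weights[l].shape[0] != self.weights[l - 1].shape[1]:
                raise ValueError(f"layer {l} fan-in does not chain")
        for w, b in zip(self.weights, self.biases):
            if b.shape != (w.shape[1],):
                raise ValueError("bias shape mismatch")
            if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
                raise ValueError("non-finite parameters")


@dataclass
class TrainConfig:
    """Full-batch training hyper-parameters.

    100 epochs is the training length used throughout; the learning rate,
    optimizer and initialization are this package's own choices (Adam 1e-3,
    He-scaled Gaussian init) — standard contemporary defaults for a
    ReLU MLP.
    """

    epochs: int = 100
    learning_rate: float = 1e-3
    optimizer_kind: str = "adam"  # "adam" or "sgd"
    hidden: tuple[int, ...] = DEFAULT_HIDDEN
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.optimizer_kind not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer_kind!r}")


@dataclass
class Prediction:
    """Output of one forward pass: logits, softmax probabilities, argmax."""

    logits: np.ndarray
    probabilities: np.ndarray
    predicted_class: int


def init_params(
    input_dim: int,
    init_seed: int,
    hidden: Sequence[int] = DEFAULT_HIDDEN,
    n_classes: int = N_CLASSES,
    dtype: str = "float32",
) -> MLPParams:
    """He-scaled Gaussian initialization (fan-in scaled), zero biases.

    Deterministic for a given seed; the repeated-experiment protocol varies
    exactly this seed.
    """
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    rng = np.random.default_rng(init_seed)
    dims = [int(input_dim), *map(int, hidden), int(n_classes)]
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        w = rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
        weights.append(w.astype(dtype))
        biases.append(np.zeros(fan_out, dtype=dtype))
    return MLPParams(weights, biases)


def _forward_batch(params: MLPParams, X: np.ndarray):
    """Forward pass keeping post-activation values for backprop."""
    acts = [X]
    h = X
    last = params.n_layers - 1
    for l, (w, b) in enumerate(zip(params.weights, params.biases)):
        h = h @ w + b
        if l < last:
            np.maximum(h, 0.0, out=h)
        acts.append(h)
    return h, acts


def softmax(z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward(params: MLPParams, x: np.ndarray) -> Prediction:
    """Classify a single edge vector."""
    x = np.asarray(x, dtype=params.weights[0].dtype)
    if x.shape != (params.input_dim,):
        raise ValueError(f"input has shape {x.shape}, expected ({params.input_dim},)")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    z, _ = _forward_batch(params, x[None, :])
    z = z[0]
    p = softmax(z.astype(np.float64))
    return Prediction(logits=z, probabilities=p,
                      predicted_class=int(np.argmax(z)))


def predict_batch(params: MLPParams, X: np.ndarray) -> np.ndarray:
    """Argmax class per row of ``X``."""
    X = np.asarray(X, dtype=params.weights[0].dtype)
    z, _ = _forward_batch(params, X)
    return np.argmax(z, axis=1)


def _backprop(params: MLPParams, acts: list[np.ndarray], dz: np.ndarray,
              need_input_grad: bool = True):
    """Gradients of an output-space seed ``dz`` w.r.t. weights, biases, input.

    ``need_input_grad=False`` skips the (large) input-layer GEMM during
    training, where the gradient w.r.t. the data is never used.
    """
    grads_w = [None] * params.n_layers
    grads_b = [None] * params.n_layers
    d = dz
    for l in range(params.n_layers - 1, -1, -1):
        grads_w[l] = acts[l].T @ d
        grads_b[l] = d.sum(axis=0)
        if l == 0 and not need_input_grad:
            d = None
            break
        d = d @ params.weights[l].T
        if l > 0:  # ReLU mask of the previous hidden layer
            d = d * (acts[l] > 0)
    return grads_w, grads_b, d


def train(
    params: MLPParams,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
) -> tuple[MLPParams, np.ndarray]:
    """Full-batch cross-entropy training; returns (trained params, loss curve).

    The loss curve holds the mean cross-entropy at the *start* of each epoch,
    so ``loss[0]`` is the initial loss and ``loss[-1]`` the loss before the
    final update.
    """
    params = params.copy()
    params.validate()
    dt = params.weights[0].dtype
    X = np.asarray(X, dtype=dt)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y shapes do not align")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data contains a single class")
    n = X.shape[0]

    if cfg.optimizer_kind == "adam":
        m_w = [np.zeros_like(w) for w in params.weights]
        v_w = [np.zeros_like(w) for w in params.weights]
        m_b = [np.zeros_like(b) for b in params.biases]
        v_b = [np.zeros_like(b) for b in params.biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8

    losses = np.empty(cfg.epochs)
    for epoch in range(cfg.epochs):
        z, acts = _forward_batch(params, X)
        p = softmax(z.astype(np.float64))
        losses[epoch] = -np.mean(np.log(p[np.arange(n), y] + 1e-300))
        dz = p.copy()
        dz[np.arange(n), y] -= 1.0
        dz = (dz / n).astype(dt)
        gw, gb, _ = _backprop(params, acts, dz, need_input_grad=False)

        if cfg.optimizer_kind == "sgd":
            for l in range(params.n_layers):
                params.weights[l] -= cfg.learning_rate * gw[l]
                params.biases[l] -= cfg.learning_rate * gb[l]
        else:
            t = epoch + 1
            corr1 = 1.0 - beta1 ** t
            corr2 = 1.0 - beta2 ** t
            for l in range(params.n_layers):
                _adam_step(params.weights[l], gw[l], m_w[l], v_w[l],
                           cfg.learning_rate, beta1, beta2, corr1, corr2, eps)
                _adam_step(params.biases[l], gb[l], m_b[l], v_b[l],
                           cfg.learning_rate, beta1, beta2, corr1, corr2, eps)
    return params, losses


def input_gradient(
    params: MLPParams,
    x: np.ndarray,
    target_class: int,
    mode: str = "probability",
) -> np.ndarray:
    """Gradient of a class output with respect to the input edge vector.

    ``probability`` mode differentiates the softmax probability of
    ``target_class``; with two classes this makes the class-0 and class-1
    gradients exact negatives of each other, which is the mechanical basis of
    the positive/negative gradient-score duality between groups.
    """
    if target_class not in (0, 1):
        raise ValueError(f"target_class must be 0 or 1, got {target_class}")
    if mode not in GRADIENT_MODES:
        raise ValueError(f"unknown gradient mode {mode!r}")
    dt = params.weights[0].dtype
    x = np.asarray(x, dtype=dt)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    z, acts = _forward_batch(params, x[None, :])
    sign = 1.0 if target_class == 0 else -1.0
    if mode == "probability":
        p = softmax(z.astype(np.float64))[0]
        # dp_c/dz = p_c * (e_c - p); with two classes this is +/- p0*p1 exactly
        g = p[0] * p[1]
        dz = np.array([[sign * g, -sign * g]], dtype=dt)
    elif mode == "logit":
        dz = np.zeros((1, 2), dtype=dt)
        dz[0, target_class] = 1.0
    else:  # margin z_c - z_{1-c}
        dz = np.array([[sign, -sign]], dtype=dt)
    _, _, dx = _backprop(params, acts, dz)
    return dx[0]


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, params: MLPParams,
                    meta: dict | None = None) -> None:
    """Write parameters (and optional config metadata) as an ``.npz`` container.

    Keys are ``W0..W{L-1}``, ``b0..b{L-1}`` plus a JSON ``meta`` string; the
    layout is stable across versions.
    """
    arrays = {f"W{l}": w for l, w in enumerate(params.weights)}
    arrays.update({f"b{l}": b for l, b in enumerate(params.biases)})
    arrays["meta"] = np.array(json.dumps(meta or {}))
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[MLPParams, dict]:
    with np.load(path, allow_pickle=False) as data:
        n_layers = sum(1 for k in data.files if k.startswith("W"))
        weights = [data[f"W{l}"] for l in range(n_layers)]
        biases = [data[f"b{l}"] for l in range(n_layers)]
        meta = json.loads(str(data["meta"]))
    params = MLPParams(weights, biases)
    params.validate()
    return params, meta
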