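"""1-D convolutional neural network for spectra, implemented in numpy.

Architecture (defaults): conv1d(16, 9) -> ReLU -> maxpool(2) -> conv1d(32, 9)
-> ReLU -> maxpool(2) -> fully_connected(d) -> softmax, trained with the
cross-entropy loss by Adam (initial learning rate 0.01, 60 epochs).  Inputs
are per-spectrum max-normalized intensity vectors.  All randomness (weight
initialisation, minibatch shuffling) derives from a single seed, so identical
seeds give identical final weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import ConfigurationError, InputError, LabelError
from .io import SpectrumSet

logger = logging.getLogger("sersml")


# ---------------------------------------------------------------------------
# Elementwise blocks
# ---------------------------------------------------------------------------


def relu(x: np.ndarray) -> np.ndarray:
    """ReLU(x) = max(0, x), elementwise."""
    return np.maximum(0.0, np.asarray(x, float))


def softmax(x: np.ndarray) -> np.ndarray:
    """Row-wise softmax; invariant to adding a constant to a row."""
    x = np.asarray(x, float)
    shifted = x - x.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(p: np.ndarray, q: np.ndarray) -> float:
    """Mean over rows of H(P, Q) = -sum_k P_k log Q_k (Q clipped at 1e-12)."""
    p = np.atleast_2d(np.asarray(p, float))
    q = np.atleast_2d(np.asarray(q, float))
    if p.shape != q.shape:
        raise InputError(f"shape mismatch {p.shape} vs {q.shape}")
    q = np.clip(q, 1e-12, None)
    return float(-(p * np.log(q)).sum(axis=1).mean())


# ---------------------------------------------------------------------------
# Layer specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Conv1D:
    filters: int
    width: int


@dataclass(frozen=True)
class ReLU:
    pass


@dataclass(frozen=True)
class MaxPool:
    width: int


@dataclass(frozen=True)
class Dense:
    units: int


@dataclass(frozen=True)
class Softmax:
    pass


def default_architecture(d: int) -> list:
    """Two conv/ReLU/pool blocks, then the class-score head.

    Raman bands at 2 cm^-1 dispersion span ~6 grid points at half maximum, so
    the signal is heavily oversampled; pooling width 4 matches that
    information density and keeps desk-scale training cheap without losing
    band-amplitude features."""
    return [
        Conv1D(8, 9), ReLU(), MaxPool(4),
        Conv1D(16, 9), ReLU(), MaxPool(4),
        Dense(d), Softmax(),
    ]


@dataclass
class TrainConfig:
    max_epochs: int = 60
    initial_learning_rate: float = 0.01
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")
        if self.initial_learning_rate <= 0:
            raise ConfigurationError("learning rate must be > 0")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")


@dataclass
class TrainingCurves:
    iteration_loss: list[float] = field(default_factory=list)
    iteration_accuracy: list[float] = field(default_factory=list)
    epoch_val_loss: list[float] = field(default_factory=list)
    epoch_val_accuracy: list[float] = field(default_factory=list)


@dataclass
class CNNModel:
    layers: list
    weights: dict[int, tuple[np.ndarray, np.ndarray]]  # layer idx -> (W, b)
    input_length: int
    class_names: list[str]

    @property
    def d(self) -> int:
        return len(self.class_names)


# ---------------------------------------------------------------------------
# Forward / backward
# ---------------------------------------------------------------------------


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """x: (N, C, L); w: (F, C, W); 'valid' convolution -> (N, F, L-W+1)."""
    windows = sliding_window_view(x, w.shape[2], axis=2)  # (N, C, L', W)
    out = np.einsum("nclw,fcw->nfl", windows, w, optimize=True)
    return out + b[None, :, None]


def _conv_backward(
    x: np.ndarray, w: np.ndarray, grad_out: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    windows = sliding_window_view(x, w.shape[2], axis=2)       # (N, C, L', W)
    grad_w = np.einsum("nclw,nfl->fcw", windows, grad_out, optimize=True)
    grad_b = grad_out.sum(axis=(0, 2))
    # full correlation of grad_out with flipped filters
    pad = w.shape[2] - 1
    padded = np.pad(grad_out, ((0, 0), (0, 0), (pad, pad)))
    gwin = sliding_window_view(padded, w.shape[2], axis=2)      # (N, F, L, W)
    grad_x = np.einsum("nflw,fcw->ncl", gwin, w[:, :, ::-1], optimize=True)
    return grad_x, grad_w, grad_b


def _pool_forward(x: np.ndarray, width: int) -> tuple[np.ndarray, np.ndarray]:
    n, c, length = x.shape
    l_out = length // width
    trimmed = x[:, :, : l_out * width].reshape(n, c, l_out, width)
    out = trimmed.max(axis=3)
    argmax = trimmed.argmax(axis=3)
    return out, argmax


def _pool_backward(
    x_shape: tuple, width: int, argmax: np.ndarray, grad_out: np.ndarray
) -> np.ndarray:
    n, c, length = x_shape
    l_out = grad_out.shape[2]
    grad = np.zeros((n, c, l_out, width))
    idx_n, idx_c, idx_l = np.indices(grad_out.shape)
    grad[idx_n, idx_c, idx_l, argmax] = grad_out
    full = np.zeros(x_shape)
    full[:, :, : l_out * width] = grad.reshape(n, c, l_out * width)
    return full


def _forward(model_layers, weights, x, keep_cache=False):
    """Run the network; x is (N, L).  Returns (probs, cache)."""
    a = x[:, None, :]  # (N, 1, L)
    cache = []
    for idx, layer in enumerate(model_layers):
        if isinstance(layer, Conv1D):
            w, b = weights[idx]
            if keep_cache:
                cache.append(("conv", idx, a))
            a = _conv_forward(a, w, b)
        elif isinstance(layer, ReLU):
            mask = a > 0
            if keep_cache:
                cache.append(("relu", idx, mask))
            a = a * mask
        elif isinstance(layer, MaxPool):
            out, argmax = _pool_forward(a, layer.width)
            if keep_cache:
                cache.append(("pool", idx, (a.shape, argmax)))
            a = out
        elif isinstance(layer, Dense):
            w, b = weights[idx]
            flat = a.reshape(a.shape[0], -1)
            if keep_cache:
                cache.append(("dense", idx, (a.shape, flat)))
            a = flat @ w + b
        elif isinstance(layer, Softmax):
            if keep_cache:
                cache.append(("softmax", idx, None))
            a = softmax(a)
        else:  # pragma: no cover
            raise ConfigurationError(f"unknown layer {layer!r}")
    return a, cache


def _backward(model_layers, weights, cache, probs, onehot):
    """Gradient of the mean cross-entropy w.r.t. every weight tensor."""
    grads = {}
    n = probs.shape[0]
    grad = (probs - onehot) / n  # softmax + cross-entropy combined
    for kind, idx, stored in reversed(cache):
        layer = model_layers[idx]
        if kind == "softmax":
            continue
        if kind == "dense":
            in_shape, flat = stored
            w, _ = weights[idx]
            grads[idx] = (flat.T @ grad, grad.sum(axis=0))
            grad = (grad @ w.T).reshape(in_shape)
        elif kind == "pool":
            in_shape, argmax = stored
            grad = _pool_backward(in_shape, layer.width, argmax, grad)
        elif kind == "relu":
            grad = grad * stored
        elif kind == "conv":
            w, _ = weights[idx]
            grad, gw, gb = _conv_backward(stored, w, grad)
            grads[idx] = (gw, gb)
    return grads


def _init_weights(layers, input_length, rng):
    """He initialisation; also validates that layer shapes chain."""
    weights = {}
    channels, length = 1, input_length
    flat_dim = None
    for idx, layer in enumerate(layers):
        if isinstance(layer, Conv1D):
            if layer.width > length:
                raise ConfigurationError("conv width exceeds input length")
            fan_in = channels * layer.width
            weights[idx] = (
                rng.normal(0.0, np.sqrt(2.0 / fan_in), (layer.filters, channels, layer.width)),
                np.zeros(layer.filters),
            )
            channels, length = layer.filters, length - layer.width + 1
        elif isinstance(layer, MaxPool):
            length = length // layer.width
            if length < 1:
                raise ConfigurationError("pooling reduced the signal to nothing")
        elif isinstance(layer, Dense):
            flat_dim = channels * length
            weights[idx] = (
                rng.normal(0.0, np.sqrt(2.0 / flat_dim), (flat_dim, layer.units)),
                np.zeros(layer.units),
            )
            channels, length = layer.units, 1
        elif isinstance(layer, (ReLU, Softmax)):
            pass
        else:  # pragma: no cover
            raise ConfigurationError(f"unknown layer {layer!r}")
    return weights


def _normalize_rows(matrix: np.ndarray) -> np.ndarray:
    peak = np.abs(matrix).max(axis=1, keepdims=True)
    peak[peak == 0] = 1.0
    return matrix / peak


def _onehot(labels: np.ndarray, class_names: list[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_names)}
    out = np.zeros((len(labels), len(class_names)))
    for row, lab in enumerate(labels):
        out[row, index[str(lab)]] = 1.0
    return out


def train_cnn(
    train: SpectrumSet,
    val: SpectrumSet | None = None,
    arch: list | None = None,
    config: TrainConfig | None = None,
) -> tuple[CNNModel, TrainingCurves]:
    """Train the CNN by Adam on the mean cross-entropy loss."""
    config = config or TrainConfig()
    class_names = train.classes
    if len(class_names) < 2:
        raise LabelError("training needs at least two classes")
    if val is not None:
        extra = set(val.classes) - set(class_names)
        if extra:
            raise LabelError(f"classes {sorted(extra)} present in val but not in train")
        if val.n_points != train.n_points:
            raise InputError("train and val must share the axis")
    layers = arch or default_architecture(len(class_names))
    rng = np.random.default_rng(config.seed)
    weights = _init_weights(layers, train.n_points, rng)

    x = _normalize_rows(train.matrix)
    t = _onehot(train.labels, class_names)
    x_val = _normalize_rows(val.matrix) if val is not None else None
    t_val = _onehot(val.labels, class_names) if val is not None else None

    # Adam state
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m = {i: (np.zeros_like(w), np.zeros_like(b)) for i, (w, b) in weights.items()}
    v = {i: (np.zeros_like(w), np.zeros_like(b)) for i, (w, b) in weights.items()}
    lr = config.initial_learning_rate
    curves = TrainingCurves()
    step = 0
    n = x.shape[0]
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            probs, cache = _forward(layers, weights, x[batch], keep_cache=True)
            grads = _backward(layers, weights, cache, probs, t[batch])
            step += 1
            for i, (gw, gb) in grads.items():
                mw, mb = m[i]
                vw, vb = v[i]
                mw = beta1 * mw + (1 - beta1) * gw
                mb = beta1 * mb + (1 - beta1) * gb
                vw = beta2 * vw + (1 - beta2) * gw**2
                vb = beta2 * vb + (1 - beta2) * gb**2
                m[i], v[i] = (mw, mb), (vw, vb)
                corr1 = 1 - beta1**step
                corr2 = 1 - beta2**step
                w, b = weights[i]
                weights[i] = (
                    w - lr * (mw / corr1) / (np.sqrt(vw / corr2) + eps),
                    b - lr * (mb / corr1) / (np.sqrt(vb / corr2) + eps),
                )
            curves.iteration_loss.append(cross_entropy(t[batch], probs))
            curves.iteration_accuracy.append(
                float((probs.argmax(1) == t[batch].argmax(1)).mean())
            )
        if x_val is not None:
            val_probs, _ = _forward(layers, weights, x_val)
            curves.epoch_val_loss.append(cross_entropy(t_val, val_probs))
            curves.epoch_val_accuracy.append(
                float((val_probs.argmax(1) == t_val.argmax(1)).mean())
            )
            logger.debug(
                "epoch %d: val loss %.4f acc %.3f",
                epoch, curves.epoch_val_loss[-1], curves.epoch_val_accuracy[-1],
            )
    model = CNNModel(layers, weights, train.n_points, class_names)
    return model, curves


def cnn_predict(
    model: CNNModel, data: SpectrumSet | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities (rows sum to 1) and argmax classes (ties -> the
    smallest class index)."""
    matrix = data.matrix if isinstance(data, SpectrumSet) else np.atleast_2d(np.asarray(data, float))
    if matrix.shape[1] != model.input_length:
        raise InputError(
            f"input length {matrix.shape[1]} does not match model ({model.input_length})"
        )
    probs, _ = _forward(model.layers, model.weights, _normalize_rows(matrix))
    classes = np.array([model.class_names[i] for i in probs.argmax(axis=1)], dtype=object)
    return probs, classes
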