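"""Minimal, deterministic neural-network engine on numpy.

Provides exactly the primitives the hierarchical classifiers need: 2-D
convolution (same padding, stride 1, via im2col), 2x2 max pooling, 2x
nearest-neighbour upsampling, dense layers with optional L2 weight decay,
ReLU/sigmoid activations, dropout, global average pooling, the Adam
optimizer, binary cross-entropy and mean-squared-error losses, and a
mini-batch training loop with validation-loss early stopping.

Design notes: layers cache their forward state, so ``backward`` must follow
a ``forward`` on the same batch.  All randomness (init, shuffling, dropout)
flows from a single ``numpy.random.Generator``, making training bit-
reproducible on one machine.  Frozen layers keep caching activations (they
stay part of the forward path) but expose no parameters to the optimizer,
so their weights are bit-identical before and after downstream training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Dense", "Conv2D", "MaxPool2", "Upsample2", "ReLU", "Sigmoid",
    "Flatten", "Reshape", "GlobalAveragePooling", "Dropout", "Sequential",
    "Adam", "bce_loss", "mse_loss", "FitConfig", "History", "fit",
]

_EPS = 1e-7

#: Default parameter/activation dtype.  float32 halves memory traffic in the
#: im2col convolutions (the dominant cost) with ample precision for training;
#: set to float64 before building layers for high-precision gradient checks.
DTYPE = np.float32


class Layer:
    """Base layer: forward/backward with cached state, optional params."""

    frozen: bool = False

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def regularization(self) -> float:
        return 0.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 l2: float = 0.0) -> None:
        self.W = _he_init(rng, n_in, (n_in, n_out))
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.l2 = l2
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def regularization(self) -> float:
        return self.l2 * float(np.sum(self.W ** 2))

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.gW[...] = self._x.T @ g + 2.0 * self.l2 * self.W
        self.gb[...] = g.sum(axis=0)
        return g @ self.W.T


class Conv2D(Layer):
    """3x3 (configurable) convolution, stride 1, 'same' zero padding.

    Input/output layout is channels-last: (N, H, W, C).
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3, l2: float = 0.0) -> None:
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.k = kernel
        self.c_in, self.c_out = c_in, c_out
        self.W = _he_init(rng, kernel * kernel * c_in, (kernel * kernel * c_in, c_out))
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.l2 = l2
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def regularization(self) -> float:
        return self.l2 * float(np.sum(self.W ** 2))

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N,H,W,C,k,k)
        return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            -1, k * k * x.shape[3]
        )

    def forward(self, x, train=False):
        if x.ndim != 4 or x.shape[3] != self.c_in:
            raise ValueError(
                f"Conv2D expected (N,H,W,{self.c_in}), got {x.shape}"
            )
        self._shape = x.shape
        self._cols = self._im2col(x)
        out = self._cols @ self.W + self.b
        n, h, w, _ = x.shape
        return out.reshape(n, h, w, self.c_out)

    def backward(self, g):
        n, h, w, c = self._shape
        k, p = self.k, self.k // 2
        g2 = g.reshape(-1, self.c_out)
        self.gW[...] = self._cols.T @ g2 + 2.0 * self.l2 * self.W
        self.gb[...] = g2.sum(axis=0)
        dcols = (g2 @ self.W.T).reshape(n, h, w, k, k, c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=dcols.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p:p + h, p:p + w, :]


class MaxPool2(Layer):
    """2x2 max pooling (even spatial dims required); ties share gradient."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even spatial dims, got {x.shape}")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        mask = (xr == out[:, :, None, :, None, :]).astype(x.dtype)
        self._mask = mask / mask.sum(axis=(2, 4), keepdims=True)
        self._shape = x.shape
        return out

    def backward(self, g):
        n, h, w, c = self._shape
        gr = g[:, :, None, :, None, :] * self._mask
        return gr.reshape(n, h, w, c)


class Upsample2(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, g):
        n, h, w, c = self._shape
        return g.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4))


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=False):
        # clip at +/-15: beyond that float32 rounds sigmoid to exactly 0/1
        # and BCE gradients are negligible; keeps outputs strictly in (0, 1)
        self._out = 1.0 / (1.0 + np.exp(-np.clip(x, -15, 15)))
        return self._out

    def backward(self, g):
        return g * self._out * (1.0 - self._out)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, target: tuple[int, ...]) -> None:
        self.target = target

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.target)

    def backward(self, g):
        return g.reshape(self._shape)


class GlobalAveragePooling(Layer):
    """(N, H, W, C) -> (N, C) spatial mean."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, g):
        n, h, w, c = self._shape
        return np.broadcast_to(g[:, None, None, :], self._shape) / (h * w)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator) -> None:
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must lie in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) / x.dtype.type(1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Sequential(Layer):
    """Ordered layer stack with feature taps and freezing."""

    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers if not l.frozen for p in l.params()]

    def grads(self):
        return [g for l in self.layers if not l.frozen for g in l.grads()]

    def regularization(self) -> float:
        return sum(l.regularization() for l in self.layers if not l.frozen)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def activations(self, x: np.ndarray) -> list[np.ndarray]:
        """Inference forward pass returning every layer's output."""
        outs = []
        for layer in self.layers:
            x = layer.forward(x, train=False)
            outs.append(x)
        return outs

    def forward_upto(self, x: np.ndarray, layer_idx: int) -> np.ndarray:
        """Output of ``layers[layer_idx]`` (inference mode)."""
        for layer in self.layers[: layer_idx + 1]:
            x = layer.forward(x, train=False)
        return x

    def grad_wrt_layer(self, x: np.ndarray, out_grad: np.ndarray, layer_idx: int) -> np.ndarray:
        """d(scalar objective)/d(output of layers[layer_idx]) via backprop."""
        self.forward(x, train=False)
        g = out_grad
        for layer in reversed(self.layers[layer_idx + 1:]):
            g = layer.backward(g)
        return g

    def freeze(self) -> None:
        for layer in self.layers:
            layer.frozen = True

    def all_params(self) -> list[np.ndarray]:
        """Every parameter array, frozen layers included."""
        out: list[np.ndarray] = []
        for l in self.layers:
            out.extend(l.all_params() if isinstance(l, Sequential) else l.params())
        return out

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.all_params()]

    def load_state(self, state: Sequence[np.ndarray]) -> None:
        params = self.all_params()
        if len(params) != len(state):
            raise ValueError("state does not match model parameters")
        for p, s in zip(params, state):
            p[...] = s


class Adam:
    """Adam optimizer over a model's (unfrozen) parameters."""

    def __init__(self, model: Layer, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in model.params()]
        self.v = [np.zeros_like(p) for p in model.params()]

    def step(self) -> None:
        self.t += 1
        for p, g, m, v in zip(self.model.params(), self.model.grads(), self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy over all entries; returns (loss, dL/dpred)."""
    p = np.clip(pred.astype(np.float64), _EPS, 1.0 - _EPS)
    t = np.asarray(target, dtype=np.float64).reshape(p.shape)
    loss = float(-np.mean(t * np.log(p) + (1 - t) * np.log(1 - p)))
    grad = ((p - t) / (p * (1 - p)) / p.size).astype(pred.dtype)
    return loss, grad


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all entries; returns (loss, dL/dpred)."""
    t = np.asarray(target, dtype=pred.dtype).reshape(pred.shape)
    diff = pred - t
    return float(np.mean(diff.astype(np.float64) ** 2)), (2.0 / diff.size) * diff


@dataclass(frozen=True)
class FitConfig:
    """Mini-batch training settings (validation-loss early stopping)."""

    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    patience: int = 3
    seed: int = 0
    restore_best: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class History:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stopped_epoch: int = 0

    def to_records(self) -> list[dict]:
        return [
            {"epoch": i + 1, "train_loss": tr, "val_loss": vl}
            for i, (tr, vl) in enumerate(zip(self.train_loss, self.val_loss))
        ]


def _eval_loss(model: Sequential, loss_fn, X, y, batch_size: int) -> float:
    total, n = 0.0, 0
    for i in range(0, len(X), batch_size):
        xb, yb = X[i:i + batch_size], y[i:i + batch_size]
        loss, _ = loss_fn(model.forward(xb, train=False), yb)
        total += loss * len(xb)
        n += len(xb)
    return total / max(n, 1)


def fit(
    model: Sequential,
    loss_fn: Callable[[np.ndarray, np.ndarray], tuple[float, np.ndarray]],
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: FitConfig = FitConfig(),
) -> History:
    """Train with Adam and early stopping on validation loss.

    Stops once the validation loss has not improved for ``patience``
    consecutive epochs, restoring the best-epoch weights (if configured).
    Raises on non-finite losses.
    """
    if len(X) == 0:
        raise ValueError("empty training set")
    X = np.asarray(X, dtype=DTYPE)
    y = np.asarray(y, dtype=DTYPE)
    X_val = np.asarray(X_val, dtype=DTYPE)
    y_val = np.asarray(y_val, dtype=DTYPE)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model, config.learning_rate)
    history = History()
    best_val, best_state, stale = np.inf, None, 0
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(X))
        epoch_loss, seen = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, yb = X[idx], y[idx]
            pred = model.forward(xb, train=True)
            loss, grad = loss_fn(pred, yb)
            loss += model.regularization()
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} (loss={loss})"
                )
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
            seen += len(idx)
        val = _eval_loss(model, loss_fn, X_val, y_val, config.batch_size)
        if not np.isfinite(val):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.train_loss.append(epoch_loss / seen)
        history.val_loss.append(val)
        history.stopped_epoch = epoch
        if val < best_val - 1e-12:
            best_val, stale = val, 0
            if config.restore_best:
                best_state = model.state()
        else:
            stale += 1
            if stale >= config.patience:
                break
    if config.restore_best and best_state is not None:
        model.load_state(best_state)
    return history
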