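"""Minimal numpy neural-network core for the activation predictors.

Implements exactly the pieces the predictor architectures need — 1-D
convolutions (same padding, via strided im2col), batch normalization, Swish,
dropout, global max-pooling over the sequence axis, dense layers, Adam, MSE —
with the training callbacks used throughout: learning-rate reduction on
training-loss plateau and early stopping on a smoothed validation loss.
Float32 throughout for speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

F32 = np.float32


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T


class Conv1D(Layer):
    """Same-padded 1-D convolution on (N, L, C_in) -> (N, L, C_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.kernel = kernel
        self.c_in = c_in
        scale = np.sqrt(2.0 / (kernel * c_in))
        self.w = (rng.standard_normal((kernel * c_in, c_out)) * scale).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel - 1 - self.pad_left

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, L, c = x.shape
        xp = np.zeros((n, L + self.kernel - 1, c), dtype=F32)
        xp[:, self.pad_left:self.pad_left + L] = x
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        # (N, L, C, k) -> (N, L, k*C)
        return np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(n, L, -1)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        self._cols = self._im2col(x.astype(F32))
        return self._cols @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, L, _ = self._shape
        g2 = grad.reshape(n * L, -1)
        self.grads[0][...] = self._cols.reshape(n * L, -1).T @ g2
        self.grads[1][...] = g2.sum(axis=0)
        dcols = (grad @ self.w.T).reshape(n, L, self.kernel, self.c_in)
        dxp = np.zeros((n, L + self.kernel - 1, self.c_in), dtype=F32)
        for j in range(self.kernel):
            dxp[:, j:j + L] += dcols[:, :, j]
        return dxp[:, self.pad_left:self.pad_left + L]


class BatchNorm(Layer):
    """Per-channel (last axis) batch normalization with running statistics."""

    def __init__(self, n_ch: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(n_ch, dtype=F32)
        self.beta = np.zeros(n_ch, dtype=F32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.run_mean = np.zeros(n_ch, dtype=F32)
        self.run_var = np.ones(n_ch, dtype=F32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._m = int(np.prod([x.shape[a] for a in axes]))
        return self.gamma * self._xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes = tuple(range(grad.ndim - 1))
        self.grads[0][...] = (grad * self._xhat).sum(axis=axes)
        self.grads[1][...] = grad.sum(axis=axes)
        m = self._m
        gxh = grad * self.gamma
        return (
            gxh - gxh.mean(axis=axes) - self._xhat * (gxh * self._xhat).mean(axis=axes)
        ) / self._std


class Swish(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._s = _sigmoid(x)
        self._x = x
        return x * self._s

    def backward(self, grad: np.ndarray) -> np.ndarray:
        s = self._s
        return grad * (s + self._x * s * (1 - s))


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class GlobalMaxPool(Layer):
    """Max over the sequence axis: (N, L, C) -> (N, C)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._arg = x.argmax(axis=1)
        self._shape = x.shape
        n, _, c = x.shape
        return x[np.arange(n)[:, None], self._arg, np.arange(c)[None, :]]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, L, c = self._shape
        dx = np.zeros(self._shape, dtype=F32)
        dx[np.arange(n)[:, None], self._arg, np.arange(c)[None, :]] = grad
        return dx


class Network:
    def __init__(self, layers: Sequence[Layer], l2: float = 0.0) -> None:
        self.layers = list(layers)
        self.l2 = l2

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        if self.l2:
            # penalize weight matrices only (ndim > 1), not biases or BN params
            for layer in self.layers:
                for p, g in zip(layer.params, layer.grads):
                    if p.ndim > 1:
                        g += 2 * self.l2 * p

    def get_weights(self) -> list[np.ndarray]:
        out = [p.copy() for p in self.params]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                out.append(layer.run_mean.copy())
                out.append(layer.run_var.copy())
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        n = len(self.params)
        for p, w in zip(self.params, weights[:n]):
            p[...] = w
        rest = iter(weights[n:])
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.run_mean = next(rest).copy()
                layer.run_var = next(rest).copy()


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    n_epochs: int = 0
    stopped_early: bool = False


def train_network(
    net: Network,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    rng: np.random.Generator,
    lr: float = 1e-3,
    max_epochs: int = 500,
    batch_size: int = 64,
    lr_drop_factor: float = 5.0,
    lr_patience: int = 20,
    early_stop_patience: int = 75,
    val_smooth_window: int = 10,
) -> TrainHistory:
    """Adam/MSE training with the plateau and early-stopping callbacks.

    Learning rate divides by `lr_drop_factor` when training loss has not
    improved for `lr_patience` epochs; training stops when the
    `val_smooth_window`-epoch moving average of validation loss has not
    improved for `early_stop_patience` epochs, restoring the best weights.
    """
    x_train = x_train.astype(F32)
    y_train = y_train.astype(F32).reshape(-1, 1)
    x_val = x_val.astype(F32)
    y_val = y_val.astype(F32).reshape(-1, 1)
    opt = Adam(net.params, lr=lr)
    hist = TrainHistory()
    n = x_train.shape[0]
    best_train = np.inf
    train_stale = 0
    best_val = np.inf
    val_stale = 0
    best_weights = net.get_weights()

    for epoch in range(max_epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, batch_size):
            idx = order[lo:lo + batch_size]
            pred = net.forward(x_train[idx], training=True)
            err = pred - y_train[idx]
            losses.append(float((err**2).mean()))
            net.backward(2 * err / err.shape[0])
            opt.step(net.grads)
        train_loss = float(np.mean(losses))
        val_pred = net.forward(x_val, training=False)
        val_loss = float(((val_pred - y_val) ** 2).mean())
        hist.train_loss.append(train_loss)
        hist.val_loss.append(val_loss)
        hist.n_epochs = epoch + 1

        if train_loss < best_train - 1e-7:
            best_train = train_loss
            train_stale = 0
        else:
            train_stale += 1
            if train_stale >= lr_patience:
                opt.lr /= lr_drop_factor
                train_stale = 0

        smoothed = float(np.mean(hist.val_loss[-val_smooth_window:]))
        if smoothed < best_val - 1e-7:
            best_val = smoothed
            val_stale = 0
            best_weights = net.get_weights()
        else:
            val_stale += 1
            if val_stale >= early_stop_patience:
                hist.stopped_early = True
                break

    net.set_weights(best_weights)
    return hist
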