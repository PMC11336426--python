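"""Minimal neural-network layers with explicit forward/backward passes.

All layers operate on float32 numpy arrays in NHWC layout (batch, height,
width, channels) for the convolutional stages and (batch, features) for the
fully connected stages; the channel-last layout keeps every inner loop a
contiguous BLAS matrix product.  Convolutions use stride 1 with "same" zero
padding and are evaluated shift-by-shift: for each of the k^2 kernel offsets
the shifted input crop is multiplied with the corresponding (C_in, C_out)
weight slice and accumulated, which costs the same FLOPs as im2col without
materializing the patch matrix.  Every layer exposes ``forward(x, train)``
and ``backward(dy)``; ``backward`` also accumulates parameter gradients, so
input-gradient saliency maps are a byproduct of the ordinary backward pass.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """Stride-1 same-padding convolution (cross-correlation, as is customary).

    Weights have shape (k, k, C_in, C_out); odd kernel sizes only.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("same padding requires an odd kernel size")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(kernel_size, kernel_size, in_channels, out_channels))
        self.params = [w.astype(np.float32), np.zeros(out_channels, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]

    @property
    def n_parameters(self) -> int:
        return self.params[0].size + self.params[1].size

    #: Patch-matrix width below which the convolution is evaluated as a
    #: single im2col matrix product; wider kernels fall back to the
    #: shift-and-accumulate scheme, whose memory traffic scales with C_in
    #: instead of C_in * k^2.
    IM2COL_MAX_COLS = 600

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        wk = self.params[0]
        if c * self.k * self.k <= self.IM2COL_MAX_COLS:
            from numpy.lib.stride_tricks import sliding_window_view

            win = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
            cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
                n * h * w, self.k * self.k * c
            )
            y = cols @ wk.reshape(-1, self.cout)
            self._cols = cols
        else:
            y = np.zeros((n * h * w, self.cout), dtype=np.float32)
            for di in range(self.k):
                for dj in range(self.k):
                    crop = xp[:, di : di + h, dj : dj + w, :].reshape(-1, c)
                    y += crop @ wk[di, dj]
            self._cols = None
        y += self.params[1]
        self._xp = xp
        self._shape = (n, h, w, c)
        return y.reshape(n, h, w, self.cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        pad = self.k // 2
        dy_flat = dy.reshape(-1, self.cout)
        wk = self.params[0]
        if self._cols is not None:
            self.grads[0][...] = (self._cols.T @ dy_flat).reshape(wk.shape)
        dxp = np.zeros_like(self._xp)
        for di in range(self.k):
            for dj in range(self.k):
                if self._cols is None:
                    crop = self._xp[:, di : di + h, dj : dj + w, :].reshape(-1, c)
                    self.grads[0][di, dj][...] = crop.T @ dy_flat
                dxp[:, di : di + h, dj : dj + w, :] += (
                    dy_flat @ wk[di, dj].T
                ).reshape(n, h, w, c)
        self.grads[1][...] = dy_flat.sum(axis=0)
        return dxp[:, pad : pad + h, pad : pad + w, :]


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2 (spatial dims must be even)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2d requires even spatial dimensions")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xr = np.ascontiguousarray(xr).reshape(n, h // 2, w // 2, 4, c)
        self._argmax = xr.argmax(axis=3)
        self._shape = (n, h, w, c)
        return np.take_along_axis(xr, self._argmax[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        dxr = np.zeros((n, h // 2, w // 2, 4, c), dtype=dy.dtype)
        np.put_along_axis(dxr, self._argmax[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dxr = dxr.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return dxr.reshape(n, h, w, c)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, np.float32(0.0))


class BatchNorm(Layer):
    """Batch normalization over the leading axes; features are the last axis."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.params = [
            np.ones(num_features, dtype=np.float32),
            np.zeros(num_features, dtype=np.float32),
        ]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    @property
    def n_parameters(self) -> int:
        return 2 * self.params[0].size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean) * inv
        self._train, self._xhat, self._inv = train, xhat, inv
        return self.params[0] * xhat + self.params[1]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = tuple(range(dy.ndim - 1))
        self.grads[0][...] = (dy * self._xhat).sum(axis=axes)
        self.grads[1][...] = dy.sum(axis=axes)
        dxhat = dy * self.params[0]
        if not self._train:
            return dxhat * self._inv
        m = dy.size // dy.shape[-1]  # elements per feature
        return (
            self._inv
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=axes)
                - self._xhat * (dxhat * self._xhat).sum(axis=axes)
            )
        ).astype(np.float32)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not (0.0 <= p < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.p, self.rng = p, rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) / (1 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(out_features, in_features))
        self.params = [w.astype(np.float32), np.zeros(out_features, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.in_features, self.out_features = in_features, out_features

    @property
    def n_parameters(self) -> int:
        return self.params[0].size + self.params[1].size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_features:
            raise ValueError(
                f"expected {self.in_features} input features, got {x.shape[1]}"
            )
        self._x = x
        return x @ self.params[0].T + self.params[1]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = dy.T @ self._x
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.params[0]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]


# ---------------------------------------------------------------------------
# Losses and optimizer
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred.reshape(-1) - target.reshape(-1)
    loss = float(np.mean(diff**2))
    grad = (2.0 * diff / diff.size).astype(np.float32).reshape(pred.shape)
    return loss, grad


class SGDNesterov:
    """Stochastic gradient descent with Nesterov momentum.

    Update rule (per parameter): v <- m*v + g; p <- p - lr * (g + m*v).
    """

    def __init__(self, params: list[np.ndarray], lr: float, momentum: float = 0.9) -> None:
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocities = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        m = self.momentum
        for p, g, v in zip(self.params, grads, self.velocities):
            v *= m
            v += g
            p -= self.lr * (g + m * v)
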