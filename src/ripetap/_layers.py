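"""Minimal 1-D CNN building blocks in numpy with manual backprop.

Each layer exposes ``forward(x, mode)`` and ``backward(dout)``; parameters
and their gradients live in ``params`` / ``grads`` dictionaries so the
optimiser can treat the network as a flat list of arrays. ``mode`` is one
of ``"train"`` (batch statistics, dropout on), ``"eval"`` (running
statistics, dropout off) or ``"mc"`` (running statistics, dropout on —
Monte-Carlo dropout at inference).

Convolution inputs are (batch, channels, length); 'same' zero padding with
odd kernels keeps the length fixed so only pooling shrinks it.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1d", "BatchNorm1d", "LeakyReLU", "MaxPool1d", "Dropout",
    "Dense", "SGDNesterov", "softmax", "cross_entropy_grad",
    "global_norm_clip",
]


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, mode: str = "train") -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """Stride-1 'same' convolution via im2col, odd kernel size."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd for 'same' padding")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel_size
        fan_in = c_in * kernel_size
        bound = np.sqrt(2.0 / fan_in)  # He init
        self.params["W"] = rng.normal(0.0, bound, size=(c_out, c_in, kernel_size))
        self.params["b"] = np.zeros(c_out)

    def forward(self, x: np.ndarray, mode: str = "train") -> np.ndarray:
        B, C, L = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        # (B, C, L, K) -> (B, L, C*K)
        col = win.transpose(0, 2, 1, 3).reshape(B, L, C * self.k)
        self._col, self._in_shape = col, x.shape
        Wmat = self.params["W"].reshape(self.c_out, -1)
        out = col @ Wmat.T + self.params["b"]
        return out.transpose(0, 2, 1)  # (B, c_out, L)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, L = self._in_shape
        dout_t = dout.transpose(0, 2, 1)  # (B, L, c_out)
        col2 = self._col.reshape(-1, C * self.k)
        dW = dout_t.reshape(-1, self.c_out).T @ col2
        self.grads["W"] = dW.reshape(self.params["W"].shape)
        self.grads["b"] = dout.sum(axis=(0, 2))
        Wmat = self.params["W"].reshape(self.c_out, -1)
        dcol = (dout_t @ Wmat).reshape(B, L, C, self.k)
        p = self.k // 2
        dxp = np.zeros((B, C, L + 2 * p))
        for kk in range(self.k):  # small kernel: cheap loop
            dxp[:, :, kk:kk + L] += dcol[:, :, :, kk].transpose(0, 2, 1)
        return dxp[:, :, p:p + L]


class BatchNorm1d(Layer):
    """Per-channel normalisation over the batch and length axes."""

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, mode: str = "train") -> np.ndarray:
        axes = (0, 2) if x.ndim == 3 else (0,)
        shape = (1, -1, 1) if x.ndim == 3 else (1, -1)
        if mode == "train":
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) / std.reshape(shape)
        self._cache = (xhat, std, axes, shape, mode)
        return self.params["gamma"].reshape(shape) * xhat + self.params["beta"].reshape(shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std, axes, shape, mode = self._cache
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        g = self.params["gamma"].reshape(shape)
        dxhat = dout * g
        if mode != "train":
            return dxhat / std.reshape(shape)
        m = np.prod([dout.shape[a] for a in axes])
        mean_d = dxhat.mean(axis=axes).reshape(shape)
        mean_dx = (dxhat * xhat).mean(axis=axes).reshape(shape)
        return (dxhat - mean_d - xhat * mean_dx) / std.reshape(shape)


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.01) -> None:
        super().__init__()
        self.slope = negative_slope

    def forward(self, x: np.ndarray, mode: str = "train") -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, self.slope * dout)


class MaxPool1d(Layer):
    """Non-overlapping max pooling; a trailing remainder is dropped."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray, mode: str = "train") -> np.ndarray:
        B, C, L = x.shape
        Lo = L // self.size
        xv = x[:, :, :Lo * self.size].reshape(B, C, Lo, self.size)
        self._argmax = xv.argmax(axis=3)
        self._in_shape = x.shape
        return xv.max(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, L = self._in_shape
        Lo = dout.shape[2]
        dx = np.zeros((B, C, Lo, self.size))
        b, c, l = np.ogrid[:B, :C, :Lo]
        dx[b, c, l, self._argmax] = dout
        out = np.zeros((B, C, L))
        out[:, :, :Lo * self.size] = dx.reshape(B, C, Lo * self.size)
        return out


class Dropout(Layer):
    """Inverted dropout; active in 'train' and 'mc' modes."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, mode: str = "train") -> np.ndarray:
        if mode == "eval" or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        bound = np.sqrt(2.0 / n_in)
        self.params["W"] = rng.normal(0.0, bound, size=(n_in, n_out))
        self.params["b"] = np.zeros(n_out)

    def forward(self, x: np.ndarray, mode: str = "train") -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, targets: np.ndarray
                       ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of integer targets plus d(loss)/d(logits)."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), targets] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    return float(loss), grad / n


def global_norm_clip(grads: list[np.ndarray], max_norm: float) -> float:
    """Rescale gradients in place so their global L2 norm is <= max_norm;
    returns the pre-clip norm."""
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads:
            g *= scale
    return total


class SGDNesterov:
    """SGD with (Nesterov) momentum:  v <- m v - lr g;
    w <- w + m v - lr g  (plain momentum uses w <- w + v)."""

    def __init__(self, momentum: float = 0.9, nesterov: bool = True) -> None:
        self.momentum = momentum
        self.nesterov = nesterov
        self._velocity: dict[int, np.ndarray] = {}

    def step(self, params: list[np.ndarray], grads: list[np.ndarray],
             lr: float) -> None:
        for i, (w, g) in enumerate(zip(params, grads)):
            v = self._velocity.get(i)
            if v is None:
                v = np.zeros_like(w)
            v = self.momentum * v - lr * g
            self._velocity[i] = v
            if self.nesterov:
                w += self.momentum * v - lr * g
            else:
                w += v
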