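"""Minimal NumPy neural-network layers with hand-written backpropagation.

Implements exactly the pieces the maturity CNN-LSTM needs - 'same' 2-D
convolution via im2col, ReLU, 2x2 max pooling, inverted dropout, a dense
layer, a single-layer LSTM, and Adam - in float32, deterministic given the
RNG that seeds the weights and the dropout masks.
"""

from __future__ import annotations

import numpy as np


def xavier_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2D:
    """3x3-style 'same' convolution, stride 1, NHWC layout."""

    def __init__(self, rng, in_channels: int, filters: int, kernel: int = 3):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.kernel = kernel
        fan_in = kernel * kernel * in_channels
        fan_out = kernel * kernel * filters
        self.W = xavier_uniform(rng, (fan_in, filters), fan_in, fan_out)
        self.b = np.zeros(filters, dtype=np.float32)
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        p = k // 2
        B, H, W, C = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # win: (B, H, W, C, k, k) -> cols (B*H*W, k*k*C)
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(B * H * W, k * k * C)
        cols = np.ascontiguousarray(cols, dtype=np.float32)
        out = cols @ self.W + self.b
        self._cache = (cols, x.shape)
        return out.reshape(B, H, W, -1)

    def backward(self, dout: np.ndarray):
        cols, (B, H, W, C) = self._cache
        k = self.kernel
        p = k // 2
        dflat = dout.reshape(B * H * W, -1).astype(np.float32)
        self.dW = cols.T @ dflat
        self.db = dflat.sum(axis=0)
        dcols = (dflat @ self.W.T).reshape(B, H, W, k, k, C)
        dxp = np.zeros((B, H + 2 * p, W + 2 * p, C), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + H, j:j + W, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p:p + H, p:p + W, :]

    @property
    def grads(self):
        return [self.dW, self.db]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2x2:
    """2x2 max pooling with stride 2 (input spatial dims must be even)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, H, W, C = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {H}x{W}")
        xr = x.reshape(B, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 5, 2, 4)
        xr = xr.reshape(B, H // 2, W // 2, C, 4)
        self._idx = np.argmax(xr, axis=-1)
        self._shape = (B, H, W, C)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray):
        B, H, W, C = self._shape
        dxr = np.zeros((B, H // 2, W // 2, C, 4), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dx = dxr.reshape(B, H // 2, W // 2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dx.reshape(B, H, W, C)


class Dropout:
    """Inverted dropout; identity when rate is 0 or at inference."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, rng: np.random.Generator | None = None, train: bool = False):
        if not train or self.rate == 0 or rng is None:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate).astype(np.float32) / (1 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dense:
    def __init__(self, rng, n_in: int, n_out: int):
        self.W = xavier_uniform(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out, dtype=np.float32)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    @property
    def grads(self):
        return [self.dW, self.db]


def _sigmoid(x):
    # clip keeps float32 exp in range; saturated gates are exactly 0/1 anyway
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


class LSTM:
    """Single-layer LSTM over (N, T, D); returns the last hidden state."""

    def __init__(self, rng, n_in: int, units: int):
        self.units = units
        self.Wx = xavier_uniform(rng, (n_in, 4 * units), n_in, 4 * units)
        self.Wh = xavier_uniform(rng, (units, 4 * units), units, 4 * units)
        self.b = np.zeros(4 * units, dtype=np.float32)

    @property
    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, T, D = x.shape
        U = self.units
        h = np.zeros((N, U), dtype=np.float32)
        c = np.zeros((N, U), dtype=np.float32)
        self._steps = []
        self._x = x
        for t in range(T):
            z = x[:, t, :] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :U])
            f = _sigmoid(z[:, U:2 * U])
            g = np.tanh(z[:, 2 * U:3 * U])
            o = _sigmoid(z[:, 3 * U:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._steps.append((h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
        return h

    def backward(self, dh: np.ndarray):
        N, T, D = self._x.shape
        U = self.units
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        dx = np.zeros_like(self._x)
        dc = np.zeros((N, U), dtype=np.float32)
        dh = dh.astype(np.float32)
        for t in reversed(range(T)):
            h_prev, c_prev, i, f, g, o, tanh_c = self._steps[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            self.dWx += self._x[:, t, :].T @ dz
            self.dWh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
            dc = dc * f
        return dx

    @property
    def grads(self):
        return [self.dWx, self.dWh, self.db]


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)
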