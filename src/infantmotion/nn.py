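"""Minimal NumPy neural-network layers with hand-derived backprop.

Only what the 1D convolutional autoencoder needs: valid-mode stride-1
Conv1d, non-overlapping MaxPool1d, ReLU, BatchNorm1d, ConvTranspose1d
with stride equal to kernel size (pure block upsampling, no output
overlap), a Linear map shared across channels, and Adam. Arrays are
(batch, channels, length) throughout; gradients are validated against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base: layers hold ``params`` and matching ``grads`` dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def _kaiming_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv1d(Layer):
    """Cross-correlation, stride 1, no padding: L_out = L_in - k + 1."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch * kernel
        self.params = {
            "W": _kaiming_uniform(rng, (out_ch, in_ch, kernel), fan_in),
            "b": _kaiming_uniform(rng, (out_ch,), fan_in),
        }

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._x = x
        win = sliding_window_view(x, self.kernel, axis=2)  # (B, C, L_out, k)
        return np.einsum("ock,bclk->bol", self.params["W"], win) + self.params["b"][:, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        win = sliding_window_view(self._x, self.kernel, axis=2)
        self.grads["W"] = np.einsum("bol,bclk->ock", dy, win)
        self.grads["b"] = dy.sum(axis=(0, 2))
        # dX is the full correlation of dY with the flipped kernel.
        k = self.kernel
        pad = np.pad(dy, ((0, 0), (0, 0), (k - 1, k - 1)))
        pwin = sliding_window_view(pad, k, axis=2)  # (B, O, L_in, k)
        return np.einsum("ock,bolk->bcl", self.params["W"][:, :, ::-1], pwin)


class ConvTranspose1d(Layer):
    """Transposed convolution with stride == kernel: L_out = k * L_in.

    With no overlap between output blocks this is a per-position linear
    upsampling, which is all the decoder's length chain 4 -> 16 -> 64
    requires.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch  # each output element sees one input position per in-channel
        self.params = {
            "W": _kaiming_uniform(rng, (in_ch, out_ch, kernel), fan_in),
            "b": _kaiming_uniform(rng, (out_ch,), fan_in),
        }

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._x = x
        B, _, L = x.shape
        y = np.einsum("cok,bcl->bolk", self.params["W"], x)
        return y.reshape(B, self.out_ch, L * self.kernel) + self.params["b"][:, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, O, Lk = dy.shape
        dyr = dy.reshape(B, O, Lk // self.kernel, self.kernel)
        self.grads["W"] = np.einsum("bolk,bcl->cok", dyr, self._x)
        self.grads["b"] = dy.sum(axis=(0, 2))
        return np.einsum("cok,bolk->bcl", self.params["W"], dyr)


class MaxPool1d(Layer):
    """Non-overlapping max pooling; a trailing remainder is dropped
    (floor division), matching the encoder's 159 -> 39 length step."""

    def __init__(self, pool: int):
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        B, C, L = x.shape
        m = (L // self.pool) * self.pool
        xr = x[:, :, :m].reshape(B, C, m // self.pool, self.pool)
        self._argmax = xr.argmax(axis=3)
        self._in_shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, Lo = dy.shape
        dx = np.zeros(self._in_shape)
        b, c, t = np.indices((B, C, Lo))
        dx[b, c, t * self.pool + self._argmax] = dy
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class BatchNorm1d(Layer):
    """Per-channel normalization over (batch, length); running statistics
    (momentum 0.1) are used at inference time."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            self._std = np.sqrt(var + self.eps)
            self._xhat = (x - mean[:, None]) / self._std[:, None]
            return self.params["gamma"][:, None] * self._xhat + self.params["beta"][:, None]
        xhat = (x - self.running_mean[:, None]) / np.sqrt(self.running_var + self.eps)[:, None]
        return self.params["gamma"][:, None] * xhat + self.params["beta"][:, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, L = dy.shape
        n = B * L
        self.grads["gamma"] = (dy * self._xhat).sum(axis=(0, 2))
        self.grads["beta"] = dy.sum(axis=(0, 2))
        g = self.params["gamma"][:, None]
        s1 = dy.sum(axis=(0, 2))[:, None]
        s2 = (dy * self._xhat).sum(axis=(0, 2))[:, None]
        return (g / (n * self._std[:, None])) * (n * dy - s1 - self._xhat * s2)


class SharedLinear(Layer):
    """Affine map applied identically to every channel: (B, C, n_in) ->
    (B, C, n_out) with one shared (n_out, n_in) weight and n_out bias."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": _kaiming_uniform(rng, (n_out, n_in), n_in),
            "b": _kaiming_uniform(rng, (n_out,), n_in),
        }

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = np.einsum("bco,bci->oi", dy, self._x)
        self.grads["b"] = dy.sum(axis=(0, 1))
        return dy @ self.params["W"]


class Flatten(Layer):
    """(B, C, L) -> (B, C*L), channel-major."""

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Reshape(Layer):
    """(B, C*L) -> (B, C, L)."""

    def __init__(self, channels: int, length: int):
        super().__init__()
        self.channels, self.length = channels, length

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        return x.reshape(x.shape[0], self.channels, self.length)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(dy.shape[0], -1)


class Adam:
    """Adam over a sequence of layers' params/grads."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for i, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                self.m[i][k] = b1 * self.m[i][k] + (1 - b1) * g
                self.v[i][k] = b2 * self.v[i][k] + (1 - b2) * g * g
                mhat = self.m[i][k] / (1 - b1 ** self.t)
                vhat = self.v[i][k] / (1 - b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
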