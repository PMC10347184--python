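"""Minimal 1-D neural-network layers with explicit reverse-mode gradients.

Everything is plain numpy float32. Layers follow the (batch, channels, length)
convention for convolutional stages and (batch, time, features) for recurrent
stages. Each layer caches what its backward pass needs during forward; call
order must therefore be forward-then-backward per batch.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


class Module:
    """Base class: parameter discovery, train/eval mode, grad reset."""

    def __init__(self):
        self.training = True

    def _children(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def modules(self):
        yield self
        for child in self._children():
            yield from child.modules()

    def parameters(self) -> list[Param]:
        params = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Param):
                    params.append(v)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def _pad_amount(kernel: int, padding: str) -> tuple[int, int]:
    if padding == "valid":
        return 0, 0
    if padding == "same":
        total = kernel - 1
        return total // 2, total - total // 2
    raise ValueError(f"unknown padding {padding!r}")


class Conv1d(Module):
    """1-D convolution (cross-correlation) with He-normal initialization."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        padding: str = "same",
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (in_channels * kernel))
        self.weight = Param(rng.normal(0.0, std, size=(out_channels, in_channels, kernel)))
        self.bias = Param(np.zeros(out_channels))
        self.stride = stride
        self.padding = padding
        self.kernel = kernel
        self.in_channels = in_channels
        self.out_channels = out_channels
        self._cache = None

    def out_length(self, length: int) -> int:
        lo, hi = _pad_amount(self.kernel, self.padding)
        return (length + lo + hi - self.kernel) // self.stride + 1

    def forward(self, x):
        lo, hi = _pad_amount(self.kernel, self.padding)
        xp = np.pad(x, ((0, 0), (0, 0), (lo, hi))) if (lo or hi) else x
        n = x.shape[0]
        windows = sliding_window_view(xp, self.kernel, axis=2)[:, :, :: self.stride]
        lout = windows.shape[2]
        # im2col once: (C*K, N*Lo); both backward GEMMs reuse it
        cols = np.ascontiguousarray(windows.transpose(1, 3, 0, 2)).reshape(
            self.in_channels * self.kernel, n * lout
        )
        w2 = self.weight.data.reshape(self.out_channels, -1)
        out = (w2 @ cols).reshape(self.out_channels, n, lout)
        out = out.transpose(1, 0, 2) + self.bias.data[None, :, None]
        self._cache = (cols, n, lout, xp.shape, (lo, hi))
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, dout):
        cols, n, lout, xp_shape, (lo, hi) = self._cache
        dout2 = np.ascontiguousarray(dout.transpose(1, 0, 2)).reshape(
            self.out_channels, n * lout
        )
        self.weight.grad += (dout2 @ cols.T).reshape(self.weight.data.shape)
        self.bias.grad += dout2.sum(axis=1)
        w2 = self.weight.data.reshape(self.out_channels, -1)
        # (C*K, N*Lo) -> viewed as (C, K, N, Lo) for the strided col2im adds
        dcols = (w2.T @ dout2).reshape(self.in_channels, self.kernel, n, lout)
        dxp = np.zeros((self.in_channels, n, xp_shape[2]), dtype=np.float32)
        span = self.stride * (lout - 1) + 1
        for k in range(self.kernel):
            dxp[:, :, k : k + span : self.stride] += dcols[:, k]
        dx = dxp.transpose(1, 0, 2)
        if lo or hi:
            dx = dx[:, :, lo : dx.shape[2] - hi if hi else None]
        return np.ascontiguousarray(dx)


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool1d(Module):
    """Temporal max pooling; overlapping windows allowed (stride < size)."""

    def __init__(self, size: int, stride: int | None = None):
        super().__init__()
        self.size = size
        self.stride = stride or size

    def out_length(self, length: int) -> int:
        return (length - self.size) // self.stride + 1

    def forward(self, x):
        windows = sliding_window_view(x, self.size, axis=2)[:, :, :: self.stride]
        out = windows.max(axis=-1)
        self._cache = (windows, out, x.shape)
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, dout):
        windows, out, x_shape = self._cache
        mask = windows == out[..., None]
        mask = mask / mask.sum(axis=-1, keepdims=True)  # split ties evenly
        contrib = dout[..., None] * mask
        dx = np.zeros(x_shape, dtype=np.float32)
        lout = out.shape[2]
        span = self.stride * (lout - 1) + 1
        for j in range(self.size):
            dx[:, :, j : j + span : self.stride] += contrib[:, :, :, j]
        return dx


class BatchNorm1d(Module):
    """Per-channel batch normalization over (batch, time)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.3):
        super().__init__()
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        self._cache = (xhat, inv_std)
        out = self.gamma.data[None, :, None] * xhat + self.beta.data[None, :, None]
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, dout):
        xhat, inv_std = self._cache
        m = dout.shape[0] * dout.shape[2]
        dgamma = (dout * xhat).sum(axis=(0, 2))
        dbeta = dout.sum(axis=(0, 2))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.data[None, :, None] * inv_std[None, :, None]
        dx = g * (dout - dbeta[None, :, None] / m - xhat * dgamma[None, :, None] / m)
        return dx.astype(np.float32)


class GlobalAvgPool1d(Module):
    def forward(self, x):
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout):
        return np.repeat(dout[:, :, None] / self._length, self._length, axis=2)


class GlobalMaxPool1d(Module):
    def forward(self, x):
        self._argmax = x.argmax(axis=2)
        self._shape = x.shape
        return x.max(axis=2)

    def backward(self, dout):
        n, c, length = self._shape
        dx = np.zeros(self._shape, dtype=np.float32)
        ni, ci = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        dx[ni, ci, self._argmax] = dout
        return dx


class Dense(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_features)
        self.weight = Param(rng.normal(0.0, std, size=(out_features, in_features)))
        self.bias = Param(np.zeros(out_features))

    def forward(self, x):
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dout):
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.data


class ToTimeMajor(Module):
    """(batch, channels, length) -> (batch, time, features)."""

    def forward(self, x):
        return np.ascontiguousarray(x.transpose(0, 2, 1))

    def backward(self, dout):
        return np.ascontiguousarray(dout.transpose(0, 2, 1))


class LastStep(Module):
    """Keep the final time step of a (batch, time, features) sequence."""

    def forward(self, x):
        self._shape = x.shape
        return x[:, -1, :]

    def backward(self, dout):
        dx = np.zeros(self._shape, dtype=np.float32)
        dx[:, -1, :] = dout
        return dx


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class LSTM(Module):
    """Single-layer LSTM over (batch, time, features), full-sequence output.

    Gate order in the packed weight matrices is input, forget, cell, output;
    the forget-gate bias starts at 1 so early training does not wash out the
    cell state.
    """

    def __init__(self, in_features: int, hidden: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(hidden)
        self.w_x = Param(rng.uniform(-bound, bound, size=(in_features, 4 * hidden)))
        self.w_h = Param(rng.uniform(-bound, bound, size=(hidden, 4 * hidden)))
        bias = np.zeros(4 * hidden)
        bias[hidden : 2 * hidden] = 1.0
        self.bias = Param(bias)
        self.hidden = hidden

    def forward(self, x):
        n, t, d = x.shape
        h_dim = self.hidden
        pre_x = x.reshape(n * t, d) @ self.w_x.data + self.bias.data
        pre_x = pre_x.reshape(n, t, 4 * h_dim)
        h = np.zeros((n, h_dim), dtype=np.float32)
        c = np.zeros((n, h_dim), dtype=np.float32)
        hs = np.empty((n, t, h_dim), dtype=np.float32)
        cache = []
        for step in range(t):
            pre = pre_x[:, step] + h @ self.w_h.data
            i = _sigmoid(pre[:, :h_dim])
            f = _sigmoid(pre[:, h_dim : 2 * h_dim])
            g = np.tanh(pre[:, 2 * h_dim : 3 * h_dim])
            o = _sigmoid(pre[:, 3 * h_dim :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((i, f, g, o, c, tanh_c, h))
            h, c = h_new, c_new
            hs[:, step] = h_new
        self._cache = (x, cache)
        return hs

    def backward(self, dout):
        x, cache = self._cache
        n, t, d = x.shape
        h_dim = self.hidden
        dh_next = np.zeros((n, h_dim), dtype=np.float32)
        dc_next = np.zeros((n, h_dim), dtype=np.float32)
        dpre_all = np.empty((n, t, 4 * h_dim), dtype=np.float32)
        dw_h = np.zeros_like(self.w_h.data)
        for step in range(t - 1, -1, -1):
            i, f, g, o, c_prev, tanh_c, h_prev = cache[step]
            dh = dout[:, step] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dpre = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dpre_all[:, step] = dpre
            dw_h += h_prev.T @ dpre
            dh_next = dpre @ self.w_h.data.T
            dc_next = dc * f
        dpre_flat = dpre_all.reshape(n * t, 4 * h_dim)
        self.w_x.grad += x.reshape(n * t, d).T @ dpre_flat
        self.w_h.grad += dw_h
        self.bias.grad += dpre_flat.sum(axis=0)
        dx = (dpre_flat @ self.w_x.data.T).reshape(n, t, d)
        return dx.astype(np.float32)
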