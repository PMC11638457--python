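"""Layers with explicit forward/backward passes.

Conventions: activations are float32 arrays shaped (N, C, H, W); every layer
caches what its backward pass needs during forward; ``backward`` consumes the
gradient w.r.t. its output and returns the gradient w.r.t. its input, writing
parameter gradients into ``Parameter.grad``.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Parameter:
    """A learnable tensor and its accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=F32)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    """Base class: stateless unless a subclass caches for backward."""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x, train=False):
        return self.forward(x, train=train)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.data[...] = state[p.name]


def _im2col(xp: np.ndarray, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (C*k*k, N*oh*ow) by k*k strided slices.

    Column-major-in-sample layout so the convolution is a single large GEMM.
    """
    n, c = xp.shape[:2]
    cols = np.empty((c, k * k, n, oh * ow), dtype=F32)
    for ki in range(k):
        for kj in range(k):
            patch = xp[:, :, ki : ki + stride * oh : stride, kj : kj + stride * ow : stride]
            cols[:, ki * k + kj] = patch.transpose(1, 0, 2, 3).reshape(c, n, -1)
    return cols.reshape(c * k * k, n * oh * ow)


def _col2im(dcols: np.ndarray, shape, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """Adjoint of _im2col; accumulates overlapping patches."""
    n, c, hp, wp = shape
    dxp = np.zeros((n, c, hp, wp), dtype=F32)
    dcols = dcols.reshape(c, k * k, n, oh, ow)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki : ki + stride * oh : stride, kj : kj + stride * ow : stride] += (
                dcols[:, ki * k + kj].transpose(1, 0, 2, 3)
            )
    return dxp


class Conv2d(Layer):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, bias=False,
                 rng: np.random.Generator | None = None, name="conv"):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.padding = kernel, stride, padding
        rng = rng or np.random.default_rng(0)
        fan_out = out_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_out), size=(out_ch, in_ch, kernel, kernel))
        self.weight = Parameter(w, name + ".weight")
        self.bias = Parameter(np.zeros(out_ch), name + ".bias") if bias else None
        self._cache = None

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.padding
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = _im2col(xp, k, s, oh, ow)  # (C*k*k, N*oh*ow)
        w2 = self.weight.data.reshape(self.out_ch, -1)
        out = w2 @ cols  # (out_ch, N*oh*ow)
        out = out.reshape(self.out_ch, n, oh, ow).transpose(1, 0, 2, 3)
        if self.bias is not None:
            out = out + self.bias.data[None, :, None, None]
        self._cache = (cols, xp.shape, oh, ow)
        return np.ascontiguousarray(out)

    def backward(self, dout):
        cols, xp_shape, oh, ow = self._cache
        n = dout.shape[0]
        d2 = np.ascontiguousarray(dout.transpose(1, 0, 2, 3)).reshape(self.out_ch, -1)
        self.weight.grad += (d2 @ cols.T).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += d2.sum(axis=1)
        w2 = self.weight.data.reshape(self.out_ch, -1)
        dcols = w2.T @ d2
        dxp = _col2im(dcols, xp_shape, self.k, self.stride, oh, ow)
        p = self.padding
        self._cache = None
        return dxp[:, :, p : xp_shape[2] - p, p : xp_shape[3] - p] if p else dxp


class BatchNorm2d(Layer):
    def __init__(self, n_ch, eps=1e-5, momentum=0.1, name="bn"):
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(n_ch), name + ".weight")
        self.beta = Parameter(np.zeros(n_ch), name + ".bias")
        self.running_mean = np.zeros(n_ch, dtype=F32)
        self.running_var = np.ones(n_ch, dtype=F32)
        self.name = name
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def state_dict(self):
        d = super().state_dict()
        d[self.name + ".running_mean"] = self.running_mean.copy()
        d[self.name + ".running_var"] = self.running_var.copy()
        return d

    def load_state_dict(self, state):
        super().load_state_dict(state)
        self.running_mean[...] = state[self.name + ".running_mean"]
        self.running_var[...] = state[self.name + ".running_var"]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(F32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        self._cache = (xhat, inv_std, train)
        return out

    def backward(self, dout):
        xhat, inv_std, train = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None] * inv_std[None, :, None, None]
        if not train:
            return dout * g
        # batch statistics backward over the (N, H, W) axes per channel
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        sum_d = dout.sum(axis=(0, 2, 3), keepdims=False)
        sum_dx = (dout * xhat).sum(axis=(0, 2, 3), keepdims=False)
        dx = g * (dout - (sum_d[None, :, None, None] + xhat * sum_dx[None, :, None, None]) / m)
        self._cache = None
        return dx


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2d(Layer):
    def __init__(self, kernel=3, stride=2, padding=1):
        self.k, self.stride, self.padding = kernel, stride, padding
        self._cache = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.padding
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        xp = np.full((n, c, h + 2 * p, w + 2 * p), -np.inf, dtype=F32)
        xp[:, :, p : p + h, p : p + w] = x
        best = np.full((n, c, oh, ow), -np.inf, dtype=F32)
        arg = np.zeros((n, c, oh, ow), dtype=np.uint8)
        for ki in range(k):
            for kj in range(k):
                patch = xp[:, :, ki : ki + s * oh : s, kj : kj + s * ow : s]
                better = patch > best
                best = np.where(better, patch, best)
                arg = np.where(better, np.uint8(ki * k + kj), arg)
        self._cache = (arg, (n, c, h, w), oh, ow)
        return best

    def backward(self, dout):
        arg, (n, c, h, w), oh, ow = self._cache
        k, s, p = self.k, self.stride, self.padding
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
        for ki in range(k):
            for kj in range(k):
                sel = arg == ki * k + kj
                dxp[:, :, ki : ki + s * oh : s, kj : kj + s * ow : s] += dout * sel
        self._cache = None
        return dxp[:, :, p : p + h, p : p + w]


class AdaptiveAvgPool2d(Layer):
    """Global average pooling to 1x1."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3), keepdims=True)

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout / (h * w), self._shape).astype(F32)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dropout(Layer):
    def __init__(self, p=0.3):
        self.p = p
        self.rng = np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        dx = dout * self._mask
        self._mask = None
        return dx


class Linear(Layer):
    def __init__(self, in_features, out_features, rng: np.random.Generator | None = None,
                 name="fc"):
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(out_features, in_features)), name + ".weight"
        )
        self.bias = Parameter(rng.uniform(-bound, bound, size=out_features), name + ".bias")
        self._x = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dout):
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        dx = dout @ self.weight.data
        self._x = None
        return dx


class Sequential(Layer):
    def __init__(self, *modules: Layer):
        self.modules = list(modules)

    def parameters(self):
        return [p for m in self.modules for p in m.parameters()]

    def forward(self, x, train=False):
        for m in self.modules:
            x = m.forward(x, train=train)
        return x

    def backward(self, dout):
        for m in reversed(self.modules):
            dout = m.backward(dout)
        return dout

    def forward_with_capture(self, x, target: Layer, train=False):
        """Forward pass returning (output, activation) where activation is
        ``target``'s output."""
        captured = None
        for m in self.modules:
            x = m.forward(x, train=train)
            if m is target:
                captured = x
        if captured is None:
            raise ValueError("target layer not found in model")
        return x, captured

    def backward_to(self, dout, target: Layer) -> np.ndarray:
        """Backpropagate from the output; return the gradient w.r.t.
        ``target``'s output (``target`` itself is not traversed)."""
        for m in reversed(self.modules):
            if m is target:
                return dout
            dout = m.backward(dout)
        raise ValueError("target layer not found in model")

    def state_dict(self):
        d = {}
        for m in self.modules:
            d.update(m.state_dict())
        return d

    def load_state_dict(self, state):
        for m in self.modules:
            m.load_state_dict(state)
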