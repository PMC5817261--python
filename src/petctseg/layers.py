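"""Minimal pure-NumPy 3D CNN engine.

Implements exactly the layer set the V-Net/W-Net architectures need —
same-padded 3x3x3 convolutions (stride 1 or 2), 2x2x2 stride-2 transposed
convolutions, 1x1x1 channel-mixing convolutions, ReLU and sigmoid — with
hand-written backpropagation and SGD-with-momentum.  Convolutions are
evaluated as im2col + BLAS matmul, which is the fastest route available in
plain NumPy at the volume sizes this package trains on.

Data layout is channels-first for a single sample: ``(C, D, H, W)``.
Batching is done by the caller (accumulate gradients over samples).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


class Param:
    """A learnable tensor with gradient and momentum buffers."""

    __slots__ = ("value", "grad", "mom")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.mom = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


_K3_OFFSETS = [(a, b, c) for a in range(3) for b in range(3) for c in range(3)]


class Conv3d(Layer):
    """Same-padded 3D convolution, kernel 3 (stride 1 or 2) or kernel 1.

    im2col is realized as 27 strided slice copies of the padded input into a
    ``(C * 27, N_out)`` matrix, which keeps the copies cache-friendly and the
    subsequent matmul in its fastest orientation.
    """

    def __init__(self, in_ch, out_ch, kernel=3, stride=1, rng=None, dtype=np.float32):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        if kernel == 1 and stride != 1:
            raise ValueError("1x1x1 convolution supports stride 1 only")
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch = int(in_ch), int(out_ch)
        self.kernel, self.stride = int(kernel), int(stride)
        self.dtype = dtype
        fan_in = in_ch * kernel**3
        self.weight = Param(
            (rng.standard_normal((out_ch, fan_in)) * np.sqrt(2.0 / fan_in)).astype(dtype)
        )
        self.bias = Param(np.zeros(out_ch, dtype=dtype))
        self._cols = None
        self._in_shape = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x):
        C, D, H, W = x.shape
        assert C == self.in_ch, f"expected {self.in_ch} channels, got {C}"
        self._in_shape = x.shape
        if self.kernel == 1:
            cols = x.reshape(C, -1)
            out_sp = (D, H, W)
        else:
            s = self.stride
            xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
            out_sp = tuple(-(-d // s) for d in (D, H, W))
            Do, Ho, Wo = out_sp
            n = Do * Ho * Wo
            cols = np.empty((C, 27, n), dtype=x.dtype)
            for j, (a, b, c) in enumerate(_K3_OFFSETS):
                sub = xp[:, a : a + s * Do : s, b : b + s * Ho : s, c : c + s * Wo : s]
                cols[:, j] = sub.reshape(C, n)
            cols = cols.reshape(C * 27, n)
        self._cols = cols
        y = self.weight.value @ cols + self.bias.value[:, None]
        return y.reshape(self.out_ch, *out_sp)

    def backward(self, dy):
        C, D, H, W = self._in_shape
        Do, Ho, Wo = dy.shape[1:]
        dyf = dy.reshape(self.out_ch, -1)
        self.weight.grad += dyf @ self._cols.T
        self.bias.grad += dyf.sum(axis=1)
        dcols = self.weight.value.T @ dyf
        if self.kernel == 1:
            return dcols.reshape(C, D, H, W)
        dxp = np.zeros((C, D + 2, H + 2, W + 2), dtype=dy.dtype)
        dcr = dcols.reshape(C, 27, -1)
        s = self.stride
        for j, (a, b, c) in enumerate(_K3_OFFSETS):
            dxp[
                :, a : a + s * Do : s, b : b + s * Ho : s, c : c + s * Wo : s
            ] += dcr[:, j].reshape(C, Do, Ho, Wo)
        return dxp[:, 1 : 1 + D, 1 : 1 + H, 1 : 1 + W]


class ConvTranspose3d(Layer):
    """2x2x2, stride-2 transposed convolution (doubles each spatial dim)."""

    def __init__(self, in_ch, out_ch, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch = int(in_ch), int(out_ch)
        fan_in = in_ch * 8
        self.weight = Param(
            (rng.standard_normal((in_ch, out_ch, 2, 2, 2)) * np.sqrt(2.0 / fan_in)).astype(dtype)
        )
        self.bias = Param(np.zeros(out_ch, dtype=dtype))
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x):
        assert x.shape[0] == self.in_ch
        self._x = x
        C, D, H, W = x.shape
        t = np.tensordot(self.weight.value, x, axes=([0], [0]))  # (F,2,2,2,D,H,W)
        y = np.ascontiguousarray(t.transpose(0, 4, 1, 5, 2, 6, 3)).reshape(
            self.out_ch, 2 * D, 2 * H, 2 * W
        )
        return y + self.bias.value[:, None, None, None]

    def backward(self, dy):
        C, D, H, W = self._x.shape
        dyr = np.ascontiguousarray(
            dy.reshape(self.out_ch, D, 2, H, 2, W, 2).transpose(0, 2, 4, 6, 1, 3, 5)
        )  # (F,2,2,2,D,H,W)
        self.weight.grad += np.tensordot(self._x, dyr, axes=([1, 2, 3], [4, 5, 6]))
        self.bias.grad += dy.sum(axis=(1, 2, 3))
        return np.tensordot(
            self.weight.value, dyr, axes=([1, 2, 3, 4], [0, 1, 2, 3])
        ).astype(dy.dtype)


class InstanceNorm3d(Layer):
    """Per-channel normalization over the spatial dimensions, with affine."""

    def __init__(self, n_ch, eps=1e-5, dtype=np.float32):
        self.eps = eps
        self.gamma = Param(np.ones(n_ch, dtype=dtype))
        self.beta = Param(np.zeros(n_ch, dtype=dtype))

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        C = x.shape[0]
        flat = x.reshape(C, -1)
        mu = flat.mean(axis=1, keepdims=True)
        var = flat.var(axis=1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (flat - mu) * self._inv
        y = self.gamma.value[:, None] * self._xhat + self.beta.value[:, None]
        return y.reshape(x.shape).astype(x.dtype)

    def backward(self, dy):
        C = dy.shape[0]
        dyf = dy.reshape(C, -1)
        xhat = self._xhat
        self.gamma.grad += (dyf * xhat).sum(axis=1)
        self.beta.grad += dyf.sum(axis=1)
        g = self.gamma.value[:, None] * self._inv
        dxhat = dyf
        dx = g * (
            dxhat
            - dxhat.mean(axis=1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=1, keepdims=True)
        )
        return dx.reshape(dy.shape).astype(dy.dtype)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


class Sigmoid(Layer):
    def forward(self, x):
        self._y = expit(x)
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.momentum = momentum

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        for p in self.params:
            p.mom = self.momentum * p.mom - self.lr * p.grad
            p.value += p.mom
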