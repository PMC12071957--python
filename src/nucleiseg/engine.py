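"""Minimal NumPy neural-network engine used by the segmentation models.

Implements exactly the layer vocabulary the architectures need — stride-1
same-padding convolutions, depthwise convolutions, 2x2 max pooling, nearest
upsampling, 2x2 stride-2 transposed convolutions, batch normalization, ReLU,
sigmoid and a channel-pooled spatial-attention gate — each with an explicit
``forward``/``backward`` pair, plus an Adam optimizer.  Tensors are NCHW
``float32`` by default; gradients are checked against finite differences in
the test suite.

Convolutions are evaluated as im2col + GEMM so the heavy lifting stays in
BLAS.  Backward passes recompute the column matrix from the cached input
instead of caching it, trading ~10% compute for a much smaller footprint.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = data
        self.grad = np.zeros_like(data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


def he_uniform(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Module:
    """Base class: a differentiable operator with trainable parameters."""

    def params(self) -> list[Param]:
        found: list[Param] = []
        for value in self.__dict__.values():
            if isinstance(value, Param):
                found.append(value)
            elif isinstance(value, Module):
                found.extend(value.params())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        found.extend(item.params())
        return found

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)

    def modules(self) -> list["Module"]:
        """This module and all submodules, in deterministic traversal order."""
        found: list[Module] = [self]
        for value in self.__dict__.values():
            if isinstance(value, Module):
                found.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        found.extend(item.modules())
        return found

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": p.data for i, p in enumerate(self.params())}
        bns = [m for m in self.modules() if isinstance(m, BatchNorm2d)]
        for i, bn in enumerate(bns):
            state[f"bn{i}_mean"] = bn.running_mean
            state[f"bn{i}_var"] = bn.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            src = state[f"p{i}"]
            if src.shape != p.data.shape:
                raise ValueError(f"shape mismatch for p{i}: {src.shape} vs {p.data.shape}")
            p.data[...] = src
        bns = [m for m in self.modules() if isinstance(m, BatchNorm2d)]
        for i, bn in enumerate(bns):
            if f"bn{i}_mean" in state:
                bn.running_mean = np.array(state[f"bn{i}_mean"], dtype=np.float64)
                bn.running_var = np.array(state[f"bn{i}_var"], dtype=np.float64)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B,C,H,W) -> (B*H*W, C*k*k) column matrix for a same-padded k x k window."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    b, c, h, w = x.shape
    # (B,C,H,W,k,k) -> (B,H,W,C,k,k) -> rows
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(b * h * w, c * k * k)


class Conv2d(Module):
    """Stride-1 same-padding convolution with bias."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        if in_ch < 1 or out_ch < 1:
            raise ValueError("channel counts must be positive")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        self.weight = Param(he_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in, dtype), "conv.w")
        self.bias = Param(np.zeros(out_ch, dtype=dtype), "conv.b")
        self._x: np.ndarray | None = None

    def forward(self, x, training=False):
        b, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {c}")
        if training:
            self._x = x
        cols = _im2col(x, self.kernel)
        wmat = self.weight.data.reshape(self.out_ch, -1)
        y = cols @ wmat.T + self.bias.data
        return np.ascontiguousarray(y.reshape(b, h, w, self.out_ch).transpose(0, 3, 1, 2))

    def backward(self, grad):
        x = self._x
        b, c, h, w = x.shape
        k = self.kernel
        gy = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(b * h * w, self.out_ch)
        cols = _im2col(x, k)
        self.weight.grad += (gy.T @ cols).reshape(self.weight.data.shape)
        self.bias.grad += gy.sum(axis=0)
        # input gradient: correlate grad with the 180deg-rotated, axis-swapped kernel
        wrot = self.weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cin, Cout, k, k)
        gcols = _im2col(grad, k)
        gx = gcols @ wrot.reshape(self.in_ch, -1).T
        return np.ascontiguousarray(gx.reshape(b, h, w, self.in_ch).transpose(0, 3, 1, 2))


class DepthwiseConv2d(Module):
    """Per-channel 3x3 (or k x k) same-padding convolution with bias."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator, dtype=np.float32):
        self.channels, self.kernel = channels, kernel
        fan_in = kernel * kernel
        self.weight = Param(he_uniform(rng, (channels, kernel, kernel), fan_in, dtype), "dw.w")
        self.bias = Param(np.zeros(channels, dtype=dtype), "dw.b")
        self._x = None

    def _windows(self, x):
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        return np.lib.stride_tricks.sliding_window_view(xp, (self.kernel, self.kernel), axis=(2, 3))

    def forward(self, x, training=False):
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        if training:
            self._x = x
        win = self._windows(x)
        return np.einsum("bchwkl,ckl->bchw", win, self.weight.data, optimize=True) + \
            self.bias.data[None, :, None, None]

    def backward(self, grad):
        win = self._windows(self._x)
        self.weight.grad += np.einsum("bchwkl,bchw->ckl", win, grad, optimize=True)
        self.bias.grad += grad.sum(axis=(0, 2, 3))
        gwin = self._windows(grad)
        wrot = self.weight.data[:, ::-1, ::-1]
        return np.einsum("bchwkl,ckl->bchw", gwin, wrot, optimize=True)


class ConvTranspose2x2(Module):
    """2x2 stride-2 transposed convolution (learned x2 upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, dtype=np.float32):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Param(he_uniform(rng, (in_ch, out_ch, 2, 2), in_ch * 4, dtype), "convT.w")
        self.bias = Param(np.zeros(out_ch, dtype=dtype), "convT.b")
        self._x = None

    def forward(self, x, training=False):
        if training:
            self._x = x
        b, c, h, w = x.shape
        y = np.einsum("bihw,iokl->bohkwl", x, self.weight.data, optimize=True)
        y = y.reshape(b, self.out_ch, 2 * h, 2 * w)
        return y + self.bias.data[None, :, None, None]

    def backward(self, grad):
        x = self._x
        b, c, h, w = x.shape
        g = grad.reshape(b, self.out_ch, h, 2, w, 2)
        self.weight.grad += np.einsum("bihw,bohkwl->iokl", x, g, optimize=True)
        self.bias.grad += grad.sum(axis=(0, 2, 3))
        return np.einsum("bohkwl,iokl->bihw", g, self.weight.data, optimize=True)


class BatchNorm2d(Module):
    """Batch normalization with running statistics (2 learnable scalars per channel)."""

    def __init__(self, channels: int, dtype=np.float32, momentum: float = 0.1, eps: float = 1e-5):
        self.channels = channels
        self.momentum, self.eps = momentum, eps
        self.gamma = Param(np.ones(channels, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self._cache = None

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if training:
            self._cache = (xhat, inv.astype(x.dtype))
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, grad):
        xhat, inv = self._cache
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.data[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gx = (g - gsum / n - xhat * (g * xhat).sum(axis=(0, 2, 3), keepdims=True) / n)
        return gx * inv[None, :, None, None]


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x, training=False):
        if training:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Module):
    def __init__(self):
        self._y = None

    def forward(self, x, training=False):
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        if training:
            self._y = y
        return y

    def backward(self, grad):
        y = self._y
        return grad * y * (1.0 - y)


class MaxPool2x2(Module):
    def __init__(self):
        self._cache = None

    def forward(self, x, training=False):
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        r = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            b, c, h // 2, w // 2, 4)
        idx = r.argmax(axis=-1)
        if training:
            self._cache = (idx, (b, c, h, w))
        return np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        idx, (b, c, h, w) = self._cache
        gwin = np.zeros((b, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(gwin, idx[..., None], grad[..., None], axis=-1)
        return gwin.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            b, c, h, w)


class Upsample2x(Module):
    """Parameter-free nearest-neighbour x2 upsampling."""

    def forward(self, x, training=False):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad):
        b, c, h, w = grad.shape
        return grad.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class SpatialAttention(Module):
    """Channel-pooled spatial gate.

    Mean and max over the channel axis give two 2-D context maps; a single
    wide (default 7x7) convolution turns them into a per-pixel logit whose
    sigmoid rescales every channel of the input.  Weight count is
    ``k*k*2 + 1`` regardless of the number of input channels.
    """

    def __init__(self, kernel: int, rng: np.random.Generator, dtype=np.float32):
        if kernel % 2 == 0:
            raise ValueError("attention kernel must be odd")
        self.kernel = kernel
        self.conv = Conv2d(2, 1, kernel, rng, dtype=dtype)
        self._cache = None

    def forward(self, x, training=False):
        avg = x.mean(axis=1, keepdims=True)
        argmax = x.argmax(axis=1)
        mx = np.take_along_axis(x, argmax[:, None], axis=1)
        s = np.concatenate([avg, mx], axis=1)
        logit = self.conv.forward(s, training=training)
        a = 1.0 / (1.0 + np.exp(-np.clip(logit, -60, 60)))
        if training:
            self._cache = (x, a, argmax)
        return x * a

    def backward(self, grad):
        x, a, argmax = self._cache
        da = (grad * x).sum(axis=1, keepdims=True)
        dlogit = da * a * (1.0 - a)
        ds = self.conv.backward(dlogit)
        gx = grad * a
        gx += ds[:, :1] / x.shape[1]
        gmax = np.zeros_like(x)
        np.put_along_axis(gmax, argmax[:, None], ds[:, 1:2], axis=1)
        return gx + gmax


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Residual(Module):
    """Identity-shortcut wrapper: y = x + body(x)."""

    def __init__(self, body: Module):
        self.body = body

    def forward(self, x, training=False):
        return x + self.body.forward(x, training=training)

    def backward(self, grad):
        return grad + self.body.backward(grad)


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float32) for p in params]
        self.v = [np.zeros_like(p.data, dtype=np.float32) for p in params]

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p.data -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
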