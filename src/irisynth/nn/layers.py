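"""Minimal CPU layer library with explicit forward/backward passes.

Every layer caches what its backward pass needs during ``forward`` and
releases the gradient with respect to its input from ``backward``.
Parameters are plain arrays with an accompanying ``grad`` buffer; the
optimizers in :mod:`irisynth.nn.optim` update them in place.

All arithmetic is float32.  Convolutions are expressed as im2col matrix
products; the scatter/gather pair used by the convolution backward pass
and the transposed convolution forward pass loops only over the k*k
kernel offsets, so the hot path stays inside BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    """A learnable array plus its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class: a differentiable block with parameters and a train flag."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        return []

    def train(self, mode: bool = True) -> None:
        self.training = mode
        for child in self.children():
            child.train(mode)

    def eval(self) -> None:
        self.train(False)

    def children(self) -> list["Module"]:
        return []

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


def gaussian_init(rng: np.random.Generator, shape: tuple[int, ...], std: float = 0.02) -> np.ndarray:
    """Zero-mean Gaussian weight initialization (std 0.02 by default)."""
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    """Strided 2-D convolution (NCHW), kernel k, stride s, symmetric zero pad p."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 4,
        stride: int = 2,
        padding: int = 1,
        rng: np.random.Generator | None = None,
        init_std: float = 0.02,
    ) -> None:
        rng = rng if rng is not None else np.random.default_rng()
        self.cin, self.cout = in_channels, out_channels
        self.k, self.s, self.p = kernel_size, stride, padding
        self.weight = Parameter(
            gaussian_init(rng, (out_channels, in_channels, kernel_size, kernel_size), init_std),
            "conv.weight",
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32), "conv.bias")
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        return (
            (h + 2 * self.p - self.k) // self.s + 1,
            (w + 2 * self.p - self.k) // self.s + 1,
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        ho, wo = self.out_hw(h, w)
        if ho <= 0 or wo <= 0:
            raise ValueError(f"input {h}x{w} too small for kernel {self.k} stride {self.s}")
        xp = np.pad(x, ((0, 0), (0, 0), (self.p, self.p), (self.p, self.p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))[:, :, :: self.s, :: self.s]
        # (b, c, ho, wo, k, k) -> (b*ho*wo, c*k*k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(b * ho * wo, -1)
        wmat = self.weight.data.reshape(self.cout, -1)
        out = cols @ wmat.T + self.bias.data
        self._cache = (cols, (b, c, h, w), (ho, wo))
        return np.ascontiguousarray(out.reshape(b, ho, wo, self.cout).transpose(0, 3, 1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, (b, c, h, w), (ho, wo) = self._cache
        g = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.weight.grad += (g.T @ cols).reshape(self.weight.data.shape)
        self.bias.grad += g.sum(axis=0)
        dcols = (g @ self.weight.data.reshape(self.cout, -1)).reshape(b, ho, wo, c, self.k, self.k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (b, c, ho, wo, k, k)
        hp, wp = h + 2 * self.p, w + 2 * self.p
        dxp = np.zeros((b, c, hp, wp), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + self.s * ho : self.s, j : j + self.s * wo : self.s] += dcols[
                    :, :, :, :, i, j
                ]
        self._cache = None
        return dxp[:, :, self.p : self.p + h, self.p : self.p + w]


class ConvTranspose2d(Module):
    """Fractionally-strided convolution; with k=4, s=2, p=1 it doubles H and W."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 4,
        stride: int = 2,
        padding: int = 1,
        rng: np.random.Generator | None = None,
        init_std: float = 0.02,
    ) -> None:
        rng = rng if rng is not None else np.random.default_rng()
        self.cin, self.cout = in_channels, out_channels
        self.k, self.s, self.p = kernel_size, stride, padding
        self.weight = Parameter(
            gaussian_init(rng, (in_channels, out_channels, kernel_size, kernel_size), init_std),
            "convT.weight",
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32), "convT.bias")
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        return (
            (h - 1) * self.s - 2 * self.p + self.k,
            (w - 1) * self.s - 2 * self.p + self.k,
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        ho, wo = self.out_hw(h, w)
        xcols = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(-1, self.cin)
        t = (xcols @ self.weight.data.reshape(self.cin, -1)).reshape(
            b, h, w, self.cout, self.k, self.k
        )
        t = t.transpose(0, 3, 1, 2, 4, 5)  # (b, cout, h, w, k, k)
        hp, wp = ho + 2 * self.p, wo + 2 * self.p
        outp = np.zeros((b, self.cout, hp, wp), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                outp[:, :, i : i + self.s * h : self.s, j : j + self.s * w : self.s] += t[
                    :, :, :, :, i, j
                ]
        out = outp[:, :, self.p : self.p + ho, self.p : self.p + wo]
        out += self.bias.data[None, :, None, None]
        self._cache = (xcols, (b, h, w), (ho, wo))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xcols, (b, h, w), (ho, wo) = self._cache
        gp = np.pad(grad, ((0, 0), (0, 0), (self.p, self.p), (self.p, self.p)))
        win = sliding_window_view(gp, (self.k, self.k), axis=(2, 3))[:, :, :: self.s, :: self.s]
        gcols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(b * h * w, -1)
        self.weight.grad += (xcols.T @ gcols).reshape(self.weight.data.shape)
        self.bias.grad += grad.sum(axis=(0, 2, 3))
        dx = (gcols @ self.weight.data.reshape(self.cin, -1).T).reshape(b, h, w, self.cin)
        self._cache = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over the spatial axes, with affine scale/shift."""

    def __init__(self, channels: int, eps: float = 1e-5) -> None:
        self.channels = channels
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32), "in.gamma")
        self.beta = Parameter(np.zeros(channels, dtype=np.float32), "in.beta")
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] * x.shape[3] < 2:
            raise ValueError("instance norm needs at least 2 spatial positions")
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        dxhat = grad * self.gamma.data[None, :, None, None]
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        self._cache = None
        return inv * (dxhat - m1 - xhat * m2)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2) -> None:
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = np.where(self._mask, grad, self.slope * grad)
        self._mask = None
        return g


class ReLU(Module):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = np.where(self._mask, grad, 0.0)
        self._mask = None
        return g


class Sigmoid(Module):
    def __init__(self) -> None:
        self._out: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x))
        self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad * self._out * (1.0 - self._out)
        self._out = None
        return g


class ChannelSoftmax(Module):
    """Softmax across the channel axis — the categorical head of the segmentor."""

    def __init__(self) -> None:
        self._out: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        out = e / e.sum(axis=1, keepdims=True)
        self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        y = self._out
        g = y * (grad - (grad * y).sum(axis=1, keepdims=True))
        self._out = None
        return g


class Dropout(Module):
    """Inverted dropout: active only in train mode, identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        g = grad * self._mask
        self._mask = None
        return g


class Sequential(Module):
    def __init__(self, *modules: Module) -> None:
        self.modules = list(modules)

    def children(self) -> list[Module]:
        return self.modules

    def parameters(self) -> list[Parameter]:
        return [p for m in self.modules for p in m.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for m in self.modules:
            x = m.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules):
            grad = m.backward(grad)
        return grad
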