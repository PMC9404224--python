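"""Minimal 3D neural-network layers with manual backpropagation.

Everything operates on float32 arrays of shape ``(N, C, D, H, W)``. Each
layer caches what its backward pass needs during ``forward`` and releases it
after ``backward``; gradients accumulate into ``Param.grad`` until the
optimizer clears them. Convolutions are evaluated as a sum of one matrix
product per kernel offset (27 for a 3x3x3 kernel), which keeps memory flat
and routes the arithmetic through BLAS.
"""

from __future__ import annotations

from itertools import product

import numpy as np

#: float32 for speed by default; tests switch to float64 for exact gradient checks
DTYPE = np.float32

__all__ = [
    "DTYPE",
    "Param",
    "Module",
    "Conv3d",
    "ConvTranspose3d",
    "InstanceNorm3d",
    "ReLU",
    "Sequential",
]


class Param:
    """A learnable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    def params(self) -> list[Param]:
        out: list[Param] = []
        for attr in vars(self).values():
            if isinstance(attr, Param):
                out.append(attr)
            elif isinstance(attr, Module):
                out.extend(attr.params())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Conv3d(Module):
    """3D convolution, cubic kernel, symmetric zero padding ``k // 2``."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        self.in_channels, self.out_channels = in_channels, out_channels
        self.k, self.stride, self.pad = k, stride, k // 2
        fan_in = in_channels * k**3
        self.weight = Param(_he_init(rng, (out_channels, in_channels, k, k, k), fan_in))
        self.bias = Param(np.zeros(out_channels, dtype=DTYPE))
        self._xp: np.ndarray | None = None

    def _out_shape(self, spatial: tuple[int, int, int]) -> tuple[int, int, int]:
        return tuple((d + 2 * self.pad - self.k) // self.stride + 1 for d in spatial)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c = x.shape[:2]
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        p, s, k = self.pad, self.stride, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        do, ho, wo = self._out_shape(x.shape[2:])
        out = np.zeros((n, self.out_channels, do, ho, wo), dtype=DTYPE)
        w = self.weight.value
        for i, j, l in product(range(k), repeat=3):
            xs = xp[
                :, :, i : i + s * (do - 1) + 1 : s,
                j : j + s * (ho - 1) + 1 : s,
                l : l + s * (wo - 1) + 1 : s,
            ]
            out += np.tensordot(w[:, :, i, j, l], xs, axes=([1], [1])).transpose(1, 0, 2, 3, 4)
        out += self.bias.value.reshape(1, -1, 1, 1, 1)
        self._xp = xp
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp = self._xp
        if xp is None:
            raise RuntimeError("backward called before forward")
        p, s, k = self.pad, self.stride, self.k
        do, ho, wo = dout.shape[2:]
        w = self.weight.value
        dxp = np.zeros_like(xp)
        for i, j, l in product(range(k), repeat=3):
            sl = (
                slice(None), slice(None),
                slice(i, i + s * (do - 1) + 1, s),
                slice(j, j + s * (ho - 1) + 1, s),
                slice(l, l + s * (wo - 1) + 1, s),
            )
            xs = xp[sl]
            self.weight.grad[:, :, i, j, l] += np.tensordot(
                dout, xs, axes=([0, 2, 3, 4], [0, 2, 3, 4])
            )
            dxp[sl] += np.tensordot(w[:, :, i, j, l], dout, axes=([0], [1])).transpose(
                1, 0, 2, 3, 4
            )
        self.bias.grad += dout.sum(axis=(0, 2, 3, 4))
        self._xp = None
        if p:
            return dxp[:, :, p:-p, p:-p, p:-p]
        return dxp


class ConvTranspose3d(Module):
    """Transposed convolution with kernel 2, stride 2 (exact 2x upsampling)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_channels, self.out_channels = in_channels, out_channels
        self.weight = Param(_he_init(rng, (out_channels, in_channels, 2, 2, 2), in_channels))
        self.bias = Param(np.zeros(out_channels, dtype=DTYPE))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, d, h, wdt = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        out = np.empty((n, self.out_channels, 2 * d, 2 * h, 2 * wdt), dtype=DTYPE)
        w = self.weight.value
        for i, j, l in product(range(2), repeat=3):
            out[:, :, i::2, j::2, l::2] = np.tensordot(
                w[:, :, i, j, l], x, axes=([1], [1])
            ).transpose(1, 0, 2, 3, 4)
        out += self.bias.value.reshape(1, -1, 1, 1, 1)
        self._x = x
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        if x is None:
            raise RuntimeError("backward called before forward")
        w = self.weight.value
        dx = np.zeros_like(x)
        for i, j, l in product(range(2), repeat=3):
            ds = dout[:, :, i::2, j::2, l::2]
            self.weight.grad[:, :, i, j, l] += np.tensordot(
                ds, x, axes=([0, 2, 3, 4], [0, 2, 3, 4])
            )
            dx += np.tensordot(w[:, :, i, j, l], ds, axes=([0], [1])).transpose(1, 0, 2, 3, 4)
        self.bias.grad += dout.sum(axis=(0, 2, 3, 4))
        self._x = None
        return dx


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalization over the spatial axes, affine."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=DTYPE))
        self.beta = Param(np.zeros(channels, dtype=DTYPE))
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (2, 3, 4)
        mean = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std)
        return self.gamma.value.reshape(1, -1, 1, 1, 1) * xhat + self.beta.value.reshape(
            1, -1, 1, 1, 1
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        xhat, inv_std = self._cache
        axes = (2, 3, 4)
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3, 4))
        self.beta.grad += dout.sum(axis=(0, 2, 3, 4))
        dxhat = dout * self.gamma.value.reshape(1, -1, 1, 1, 1)
        m1 = dxhat.mean(axis=axes, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
        self._cache = None
        return inv_std * (dxhat - m1 - xhat * m2)


class ReLU(Module):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.zeros((), dtype=x.dtype))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            raise RuntimeError("backward called before forward")
        out = np.where(self._mask, dout, np.zeros((), dtype=dout.dtype))
        self._mask = None
        return out


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for m in self.modules:
            x = m.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules):
            dout = m.backward(dout)
        return dout
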