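"""Res-UNet: a U-Net encoder-decoder with residual encoder blocks.

The encoder extracts features with residual blocks (two
convolution-normalize-activate stages whose input is added to their output,
through a 1x1 projection when the channel count changes); resolution halves
between levels via strided convolution. The decoder upsamples with
transposed convolutions, concatenates the same-level encoder output (the
U-Net skip connection) and refines with plain convolution blocks. A 1x1
head emits per-class score maps at the input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Conv3d, ConvTranspose3d, InstanceNorm3d, Module, Param, ReLU, Sequential

__all__ = ["NetworkSpec", "ResidualBlock", "ResUNet", "build_network"]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters of the Res-UNet."""

    input_channels: int = 1
    num_classes: int = 2
    depth: int = 4
    base_channels: int = 16
    residual_blocks_per_level: int = 1
    normalization: str = "instance"
    nonlinearity: str = "relu"

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.normalization not in ("instance",):
            raise ValueError(f"unsupported normalization {self.normalization!r}")
        if self.nonlinearity not in ("relu",):
            raise ValueError(f"unsupported nonlinearity {self.nonlinearity!r}")

    @property
    def channels(self) -> list[int]:
        return [self.base_channels * 2**i for i in range(self.depth)]

    def check_patch_size(self, patch_size) -> None:
        div = 2 ** (self.depth - 1)
        bad = [d for d in patch_size if d % div != 0]
        if bad:
            raise ValueError(
                f"patch size {tuple(patch_size)} not divisible by 2^(depth-1)={div}"
            )


class ResidualBlock(Module):
    """conv-norm-act, conv-norm, plus identity (or 1x1-projected) input, act."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv1 = Conv3d(cin, cout, 3, rng=rng)
        self.norm1 = InstanceNorm3d(cout)
        self.act1 = ReLU()
        self.conv2 = Conv3d(cout, cout, 3, rng=rng)
        self.norm2 = InstanceNorm3d(cout)
        self.proj = Conv3d(cin, cout, 1, rng=rng) if cin != cout else None
        self.act_out = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.act1(self.norm1(self.conv1(x)))
        h = self.norm2(self.conv2(h))
        skip = self.proj(x) if self.proj is not None else x
        return self.act_out(h + skip)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.act_out.backward(dout)
        dskip = self.proj.backward(d) if self.proj is not None else d
        dh = self.conv1.backward(
            self.norm1.backward(self.act1.backward(self.conv2.backward(self.norm2.backward(d))))
        )
        return dh + dskip


class _ConvBlock(Module):
    """Two plain conv-norm-act stages (decoder refinement)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.seq = Sequential(
            Conv3d(cin, cout, 3, rng=rng),
            InstanceNorm3d(cout),
            ReLU(),
            Conv3d(cout, cout, 3, rng=rng),
            InstanceNorm3d(cout),
            ReLU(),
        )

    def forward(self, x):
        return self.seq.forward(x)

    def backward(self, dout):
        return self.seq.backward(dout)


class ResUNet(Module):
    def __init__(self, spec: NetworkSpec, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x0E7]))
        self.spec = spec
        ch = spec.channels
        self.enc = []
        for lvl in range(spec.depth):
            cin = spec.input_channels if lvl == 0 else ch[lvl]
            blocks = []
            for b in range(spec.residual_blocks_per_level):
                blocks.append(ResidualBlock(cin if b == 0 else ch[lvl], ch[lvl], rng))
            self.enc.append(Sequential(*blocks))
        self.down = [Conv3d(ch[l - 1], ch[l], 3, stride=2, rng=rng) for l in range(1, spec.depth)]
        self.up = [ConvTranspose3d(ch[l + 1], ch[l], rng=rng) for l in range(spec.depth - 1)]
        self.dec = [_ConvBlock(2 * ch[l], ch[l], rng) for l in range(spec.depth - 1)]
        self.head = Conv3d(ch[0], spec.num_classes, 1, rng=rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        spec = self.spec
        spec.check_patch_size(x.shape[2:])
        feats = [self.enc[0](x)]
        for lvl in range(1, spec.depth):
            feats.append(self.enc[lvl](self.down[lvl - 1](feats[-1])))
        h = feats[-1]
        for lvl in range(spec.depth - 2, -1, -1):
            u = self.up[lvl](h)
            h = self.dec[lvl](np.concatenate([u, feats[lvl]], axis=1))
        return self.head(h)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        spec = self.spec
        ch = spec.channels
        d = self.head.backward(dout)
        grad_enc: list[np.ndarray | None] = [None] * spec.depth
        for lvl in range(spec.depth - 1):  # reverse decoding order
            d = self.dec[lvl].backward(d)
            du, dskip = d[:, : ch[lvl]], d[:, ch[lvl] :]
            grad_enc[lvl] = dskip
            d = self.up[lvl].backward(np.ascontiguousarray(du))
        # d is now the gradient at the bottleneck encoder output
        for lvl in range(spec.depth - 1, 0, -1):
            d = self.down[lvl - 1].backward(self.enc[lvl].backward(d))
            d = d + grad_enc[lvl - 1]
        return self.enc[0].backward(d)

    # --- parameter (de)serialization -------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.params()
        if len(arrays) != len(params):
            raise ValueError(f"checkpoint has {len(arrays)} tensors, model needs {len(params)}")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError(f"shape mismatch {p.value.shape} vs {a.shape}")
            p.value[...] = a


def build_network(spec: NetworkSpec, seed: int = 0) -> ResUNet:
    """Instantiate a Res-UNet with seeded He-initialized weights."""
    return ResUNet(spec, seed=seed)
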