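"""Small convolutional building blocks and a configurable N-D U-Net."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, avg_pool, concat, conv, upsample_nearest

__all__ = ["Module", "ConvLayer", "ConvBlock", "UNet"]


class Module:
    """Base class: parameter collection and (de)serialization."""

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self):
        return [p.data.copy() for p in self.parameters()]

    def load_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = a.copy()

    def kernel_sq_norm(self) -> float:
        """Sum of squared convolution kernel entries (weight-decay norm)."""
        return float(sum(np.sum(p.data**2) for p in self.parameters()))


class ConvLayer(Module):
    """'Same' N-D convolution with optional bias, He-style seeded init."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int = 3, nd: int = 3,
                 rng=None, bias: bool = True, gain: float = 1.0):
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_ch * ksize**nd
        w = rng.standard_normal((out_ch, in_ch) + (ksize,) * nd) * gain * np.sqrt(2.0 / fan_in)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv(x, self.weight, self.bias)


class ConvBlock(Module):
    """Two conv + leaky-ReLU layers."""

    def __init__(self, in_ch, out_ch, nd, rng, ksize=3):
        self.c1 = ConvLayer(in_ch, out_ch, ksize, nd, rng)
        self.c2 = ConvLayer(out_ch, out_ch, ksize, nd, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.c2(self.c1(x).leaky_relu()).leaky_relu()


class UNet(Module):
    """Encoder-decoder with skip connections, ``levels`` resolutions.

    Channel width doubles per level from ``base_ch``.  Spatial dims must
    be divisible by ``2**(levels-1)`` (inputs are padded to a multiple
    of 16 upstream).
    """

    def __init__(self, nd: int = 3, in_ch: int = 2, out_ch: int = 2,
                 base_ch: int = 16, levels: int = 3, seed: int = 0,
                 final_gain: float = 1.0):
        rng = np.random.default_rng(seed)
        self.nd = nd
        self.levels = levels
        self.down = []
        ch = in_ch
        for lv in range(levels):
            width = base_ch * 2**lv
            self.down.append(ConvBlock(ch, width, nd, rng))
            ch = width
        self.up = []
        for lv in range(levels - 2, -1, -1):
            width = base_ch * 2**lv
            self.up.append(ConvBlock(ch + width, width, nd, rng))
            ch = width
        self.head = ConvLayer(ch, out_ch, 1, nd, rng, gain=final_gain)

    def __call__(self, x: Tensor) -> Tensor:
        skips = []
        for lv, block in enumerate(self.down):
            x = block(x)
            if lv < self.levels - 1:
                skips.append(x)
                x = avg_pool(x, 2)
        for block, skip in zip(self.up, reversed(skips)):
            x = upsample_nearest(x, 2)
            x = block(concat([skip, x], axis=0))
        return self.head(x)
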