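"""Double-attention residual U-blocks.

Each block is a small encoder/decoder ("U") whose output is added to a
3x3 projection of its own input (the residual path).  Two flavours:

* :class:`AttentiveRSU` (depth L in {4..7}) resamples internally with
  2x2 max pooling / bilinear upsampling.  Every skip connection passes
  through an :class:`~vesselseg.attention.AttentionGate` before being
  concatenated with the upsampled deeper feature, and the topmost
  decoder output passes through spatial attention (SAM) before the
  residual addition.  An input of spatial size H x W requires H and W
  divisible by ``2**(L-2)``.
* :class:`AttentiveRSU4F` keeps the spatial size at every layer and
  widens the receptive field with dilated convolutions instead
  (encoder dilations 1, 2, 4, 8; decoder 4, 2, 1).  Skips are gated at
  equal resolution and the decoder output passes through channel
  attention (CAM) before the residual addition.  The dilated encoder
  chain of 3x3 kernels has a 1 + 2*(1+2+4+8) = 31-pixel receptive
  field along each axis.

Attention can be toggled off per mechanism (``use_gate`` /
``use_sam`` / ``use_cam``), reducing the block to a plain residual
U-block with unchanged shapes — the ablation configuration.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .attention import AttentionGate, ChannelAttention, SpatialAttention
from .nn import ConvBNReLU, Module, ModuleList

__all__ = ["AttentiveRSU", "AttentiveRSU4F"]


class AttentiveRSU(Module):
    """Residual U-block of depth ``L`` with gated skips and output SAM."""

    def __init__(self, depth: int, in_channels: int, mid_channels: int,
                 out_channels: int, rng: np.random.Generator,
                 use_gate: bool = True, use_sam: bool = True):
        super().__init__()
        if depth not in (4, 5, 6, 7):
            raise ValueError("depth must be in {4, 5, 6, 7}")
        self.depth = depth
        self.use_gate = use_gate
        self.use_sam = use_sam
        self.proj = ConvBNReLU(in_channels, out_channels, rng)
        enc = [ConvBNReLU(out_channels, mid_channels, rng)]
        enc += [ConvBNReLU(mid_channels, mid_channels, rng)
                for _ in range(depth - 2)]
        self.encoders = ModuleList(enc)  # L-1 units, pools between them
        self.gates = ModuleList(
            [AttentionGate(mid_channels, mid_channels, rng)
             for _ in range(depth - 2)] if use_gate else [])
        dec = [ConvBNReLU(2 * mid_channels, mid_channels, rng)
               for _ in range(depth - 3)]
        dec.append(ConvBNReLU(2 * mid_channels, out_channels, rng))
        self.decoders = ModuleList(dec)  # ordered deepest level first
        self.sam = SpatialAttention(rng) if use_sam else None

    def forward(self, x: Tensor) -> Tensor:
        H, W = x.shape[2], x.shape[3]
        factor = 2 ** (self.depth - 2)
        if H % factor or W % factor:
            raise ValueError(f"input must be divisible by 2^(L-2) = {factor}")
        f0 = self.proj(x)
        feats = []
        h = f0
        for i, enc in enumerate(self.encoders):
            if i > 0:
                h = ad.max_pool2x2(h)
            h = enc(h)
            feats.append(h)
        g = feats[-1]
        # walk back up: deepest skip first
        for i, (skip, dec) in enumerate(zip(reversed(feats[:-1]), self.decoders)):
            gated = self.gates[i](skip, g) if self.use_gate else skip
            up = ad.upsample_bilinear(g, (skip.shape[2], skip.shape[3]))
            g = dec(ad.concat([gated, up], axis=1))
        if self.sam is not None:
            g = self.sam(g)
        return g + f0


class AttentiveRSU4F(Module):
    """Dilated residual U-block: no resampling, output CAM."""

    DILATIONS = (1, 2, 4, 8)

    def __init__(self, in_channels: int, mid_channels: int, out_channels: int,
                 rng: np.random.Generator, use_gate: bool = True,
                 use_cam: bool = True,
                 dilation_rates: tuple[int, ...] = (2, 4, 8)):
        super().__init__()
        self.use_gate = use_gate
        self.use_cam = use_cam
        rates = (1,) + tuple(dilation_rates)
        self.proj = ConvBNReLU(in_channels, out_channels, rng)
        enc = [ConvBNReLU(out_channels, mid_channels, rng, dilation=rates[0])]
        enc += [ConvBNReLU(mid_channels, mid_channels, rng, dilation=d)
                for d in rates[1:]]
        self.encoders = ModuleList(enc)
        self.gates = ModuleList(
            [AttentionGate(mid_channels, mid_channels, rng)
             for _ in range(len(rates) - 1)] if use_gate else [])
        dec_rates = rates[-2::-1]  # mirror, deepest first: 4, 2, 1
        dec = [ConvBNReLU(2 * mid_channels, mid_channels, rng, dilation=d)
               for d in dec_rates[:-1]]
        dec.append(ConvBNReLU(2 * mid_channels, out_channels, rng,
                              dilation=dec_rates[-1]))
        self.decoders = ModuleList(dec)
        self.cam = ChannelAttention(out_channels, rng) if use_cam else None

    def forward(self, x: Tensor, trace: list | None = None) -> Tensor:
        f0 = self.proj(x)
        feats = []
        h = f0
        for enc in self.encoders:
            h = enc(h)
            feats.append(h)
            if trace is not None:
                trace.append(h.shape)
        g = feats[-1]
        for i, (skip, dec) in enumerate(zip(reversed(feats[:-1]), self.decoders)):
            gated = self.gates[i](skip, g) if self.use_gate else skip
            g = dec(ad.concat([gated, g], axis=1))
            if trace is not None:
                trace.append(g.shape)
        if self.cam is not None:
            g = self.cam(g)
        return g + f0
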