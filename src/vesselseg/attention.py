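"""Attention primitives: the skip-connection attention gate and the two
halves of the Convolutional Block Attention Module (CBAM).

All three are soft gating operators: they compute a coefficient map with
values strictly inside (0, 1) (a sigmoid output) and rescale the input
feature map by it, so each preserves the input's shape exactly and acts
linearly on the features once the coefficients are frozen.

* :class:`AttentionGate` — feature-channel attention on a skip
  connection.  The skip feature ``x`` (resolution H x W) and the deeper
  gating feature ``g`` (same resolution or exactly half) are projected
  by 1x1 convolutions to a shared intermediate width, added, passed
  through ReLU, a 1x1 convolution to a single channel, and a sigmoid.
  The resulting per-pixel coefficient map scales every channel of ``x``.
* :class:`SpatialAttention` (SAM) — per-pixel coefficients from the
  channel-wise mean and max maps, stacked and convolved with one 7x7
  kernel.
* :class:`ChannelAttention` (CAM) — per-channel coefficients from
  global mean and max pooling, pushed through a shared two-layer
  bottleneck transform (C -> C/r -> C) and summed before the sigmoid.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Conv2d, Module

__all__ = ["AttentionGate", "SpatialAttention", "ChannelAttention"]


class AttentionGate(Module):
    """Additive attention gate for skip connections.

    Parameters
    ----------
    x_channels : channels of the skip feature being gated.
    g_channels : channels of the (deeper) gating feature.
    inter_channels : width of the shared projection; defaults to half of
        ``x_channels`` (at least 1).
    rng : seeded generator for weight initialization.
    """

    def __init__(self, x_channels: int, g_channels: int,
                 rng: np.random.Generator, inter_channels: int | None = None):
        super().__init__()
        if inter_channels is None:
            inter_channels = max(x_channels // 2, 1)
        if inter_channels < 1:
            raise ValueError("inter_channels must be >= 1")
        self.w_x = Conv2d(x_channels, inter_channels, 1, rng)
        self.w_g = Conv2d(g_channels, inter_channels, 1, rng)
        self.psi = Conv2d(inter_channels, 1, 1, rng)

    def coefficients(self, x: Tensor, g: Tensor) -> Tensor:
        """The single-channel attention map alpha at x's resolution."""
        if x.shape[0] != g.shape[0]:
            raise ValueError("batch mismatch")
        H, W = x.shape[2], x.shape[3]
        gh, gw = g.shape[2], g.shape[3]
        if (gh, gw) == (H, W):
            proj_g = self.w_g(g)
        elif (gh * 2, gw * 2) == (H, W):
            proj_g = ad.upsample_bilinear(self.w_g(g), (H, W))
        else:
            raise ValueError("incompatible gate resolution")
        pre = ad.relu(self.w_x(x) + proj_g)
        return ad.sigmoid(self.psi(pre))

    def forward(self, x: Tensor, g: Tensor) -> Tensor:
        return x * self.coefficients(x, g)


class SpatialAttention(Module):
    """CBAM spatial attention (SAM): where to look, per pixel."""

    def __init__(self, rng: np.random.Generator, kernel_size: int = 7):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel must be odd")
        self.conv = Conv2d(2, 1, kernel_size, rng)

    def coefficients(self, x: Tensor) -> Tensor:
        pooled = ad.concat([ad.channel_mean(x), ad.channel_max(x)], axis=1)
        return ad.sigmoid(self.conv(pooled))

    def forward(self, x: Tensor) -> Tensor:
        return x * self.coefficients(x)


class ChannelAttention(Module):
    """CBAM channel attention (CAM): which channels matter, globally.

    Both pooling branches share one two-layer bottleneck (implemented as
    1x1 convolutions on the pooled [B,C,1,1] maps); their outputs are
    summed before the sigmoid.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 16):
        super().__init__()
        if reduction < 1:
            raise ValueError("reduction must be >= 1")
        hidden = max(1, channels // reduction)
        self.fc1 = Conv2d(channels, hidden, 1, rng)
        self.fc2 = Conv2d(hidden, channels, 1, rng)

    def _branch(self, pooled: Tensor) -> Tensor:
        return self.fc2(ad.relu(self.fc1(pooled)))

    def coefficients(self, x: Tensor) -> Tensor:
        mean_b = self._branch(ad.spatial_mean(x))
        max_b = self._branch(ad.spatial_max(x))
        return ad.sigmoid(mean_b + max_b)

    def forward(self, x: Tensor) -> Tensor:
        return x * self.coefficients(x)
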