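"""Convolutional block attention (CBAM): channel gating then spatial gating.

The fused band-stacked tensor is treated as a (B, C, H, W) image with the
five frequency bands as channels.  Channel attention squeezes (H, W) by both
average and max pooling, passes the two descriptors through a shared
two-layer MLP, sums them and applies a sigmoid; spatial attention pools over
the channel axis, concatenates the mean and max maps and convolves with a
7x7 kernel before the sigmoid.  Both gates lie strictly in (0, 1), so the
refinement only ever attenuates.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["CbamConfig", "ChannelAttention", "SpatialAttention", "CBAM"]


@dataclass
class CbamConfig:
    n_channels: int = 5
    reduction: int = 4
    spatial_kernel: int = 7
    mlp_bias: bool = True

    def __post_init__(self):
        if self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be odd to preserve shape")

    @property
    def hidden_dim(self) -> int:
        return max(1, ceil(self.n_channels / self.reduction))


class ChannelAttention(nn.Module):
    def __init__(self, cfg: CbamConfig, rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(cfg.n_channels, cfg.hidden_dim, rng,
                             bias=cfg.mlp_bias)
        self.fc2 = nn.Linear(cfg.hidden_dim, cfg.n_channels, rng,
                             bias=cfg.mlp_bias)

    def _mlp(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())

    def forward(self, x: Tensor) -> Tensor:
        """(B, C, H, W) -> channel gate (B, C, 1, 1)."""
        B, C = x.shape[0], x.shape[1]
        flat = x.reshape(B, C, -1)
        avg = self._mlp(flat.mean(axis=-1))
        mx = self._mlp(flat.max(axis=-1))
        return (avg + mx).sigmoid().reshape(B, C, 1, 1)


class SpatialAttention(nn.Module):
    def __init__(self, cfg: CbamConfig, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, cfg.spatial_kernel, rng,
                              padding=(cfg.spatial_kernel - 1) // 2)

    def forward(self, x: Tensor) -> Tensor:
        """(B, C, H, W) -> spatial gate (B, 1, H, W)."""
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        pooled = nn.concat([avg, mx], axis=1)
        return self.conv(pooled).sigmoid()


class CBAM(nn.Module):
    """Sequential channel-then-spatial refinement:
    ``F'' = (F * Mc(F)) * Ms(F * Mc(F))``."""

    def __init__(self, cfg: CbamConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.channel = ChannelAttention(cfg, rng)
        self.spatial = SpatialAttention(cfg, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
        refined = x * self.channel(x)
        return refined * self.spatial(refined)
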