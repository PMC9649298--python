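"""Reusable network blocks: double-conv unit, DropBlock, spatial attention.

Each encoder/decoder stage is a Conv3x3 -> DropBlock -> BatchNorm -> ReLU
unit applied twice.  DropBlock is structured dropout: during training it
zeroes contiguous square regions of the feature map (forcing the network
not to rely on any single neighbourhood, which matters for thin vessels)
and rescales the survivors so the expected activation mass is unchanged.

The spatial attention gate pools the feature map channel-wise by max and
mean, pushes the 2-channel result through a 7x7 convolution and a
sigmoid, and multiplies the input by the resulting single-channel map:

    SA = F * sigma(f7([maxpool_c(F); avgpool_c(F)]))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter

from . import tensor as T
from .nn import BatchNorm2d, Conv2d, Module
from .tensor import Tensor


@dataclass
class DropBlockConfig:
    """DropBlock hyperparameters.

    block_size : odd positive int, side of the square regions dropped.
    keep_prob : probability mass kept; 1.0 disables dropping entirely.
    """

    block_size: int = 7
    keep_prob: float = 0.82

    def validate(self):
        if self.block_size < 1 or self.block_size % 2 == 0:
            raise ValueError("block_size must be an odd positive integer")
        if not (0.0 < self.keep_prob <= 1.0):
            raise ValueError("keep_prob must lie in (0, 1]")


def validate_feature_map(x) -> None:
    """Check the (batch, channel, row, col) contract and finiteness."""
    data = x.data if isinstance(x, Tensor) else np.asarray(x)
    if data.ndim != 4:
        raise ValueError(f"feature map must be 4-axis, got ndim={data.ndim}")
    if min(data.shape) < 1:
        raise ValueError("all feature-map extents must be >= 1")
    if not np.all(np.isfinite(data)):
        raise FloatingPointError("feature map contains non-finite values")


def drop_block(x, cfg: DropBlockConfig, training: bool,
               rng: np.random.Generator):
    """Apply DropBlock to a (B, C, H, W) tensor.

    Seed points are sampled Bernoulli(gamma) on the region where a full
    block fits, expanded to block_size x block_size squares, and surviving
    activations are rescaled by count/kept per feature map so that
    E[output] = input.  Identity at inference or when keep_prob == 1.
    """
    cfg.validate()
    x = T.as_tensor(x)
    if not training or cfg.keep_prob >= 1.0:
        return x
    B, C, H, W = x.shape
    bs = cfg.block_size
    if bs > H or bs > W:
        raise ValueError(f"block_size {bs} exceeds spatial extents {(H, W)}")
    gamma = ((1.0 - cfg.keep_prob) / bs**2
             * (H * W) / ((H - bs + 1) * (W - bs + 1)))
    seeds = np.zeros((B, C, H, W), dtype=bool)
    inner = rng.random((B, C, H - bs + 1, W - bs + 1)) < gamma
    off = bs // 2
    seeds[:, :, off:off + H - bs + 1, off:off + W - bs + 1] = inner
    dropped = maximum_filter(seeds, size=(1, 1, bs, bs))
    mask = (~dropped).astype(np.float64)
    kept = mask.sum(axis=(2, 3), keepdims=True)
    scale = np.where(kept > 0, (H * W) / np.maximum(kept, 1.0), 0.0)
    return T.mul(x, mask * scale)


class DropBlock(Module):
    def __init__(self, cfg: DropBlockConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self._cfg = cfg
        self._rng = rng

    def forward(self, x):
        return drop_block(x, self._cfg, self._training, self._rng)


@dataclass
class ConvBlockConfig:
    in_channels: int
    out_channels: int
    dropblock: DropBlockConfig


class ConvBlock(Module):
    """Conv3x3 -> DropBlock -> BN -> ReLU, applied ``n_convs`` times.

    Two units by default (the standard U-shape double conv); spatial
    extents are preserved by 1-pixel zero padding.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 dropblock: DropBlockConfig | None = None, *,
                 n_convs: int = 2, rng: np.random.Generator | None = None,
                 dropblock_rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels < 1 or out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        dropblock = dropblock or DropBlockConfig()
        rng = rng or np.random.default_rng(0)
        self._in_channels = in_channels
        self.convs = []
        self.norms = []
        self.drops = []
        cin = in_channels
        for _ in range(max(1, n_convs)):
            self.convs.append(Conv2d(cin, out_channels, 3, rng=rng))
            self.norms.append(BatchNorm2d(out_channels))
            self.drops.append(DropBlock(dropblock,
                                        dropblock_rng or np.random.default_rng(0)))
            cin = out_channels

    def forward(self, x):
        validate_feature_map(x)
        x = T.as_tensor(x)
        if x.shape[1] != self._in_channels:
            raise ValueError(
                f"expected {self._in_channels} input channels, got {x.shape[1]}")
        for conv, drop, norm in zip(self.convs, self.drops, self.norms):
            x = T.relu(norm(drop(conv(x))))
        return x


class SpatialAttention(Module):
    """Single-channel sigmoid gate from channel-wise max/mean pooling."""

    def __init__(self, kernel_size: int = 7, *,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(2, 1, kernel_size, rng=rng, bias=True)

    def forward(self, f):
        """Return ``(SA, att)``: the gated feature and the attention map."""
        f = T.as_tensor(f)
        pooled = T.concat([T.channel_max(f), T.channel_mean(f)], axis=1)
        att = T.sigmoid(self.conv(pooled))
        return T.mul(f, att), att


def spatial_attention(f, *, rng: np.random.Generator | None = None):
    """Functional convenience wrapper around :class:`SpatialAttention`."""
    return SpatialAttention(rng=rng)(f)
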