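"""Bottleneck context modules: atrous convolution, DAC, MKP and fusion.

Atrous (dilated) convolution samples the input with a tap spacing of r
between kernel elements,

    y[i] = sum_k x[i + r k] w[k],

so a 3x3 filter at rate r covers an effective (2r+1)x(2r+1) receptive
field without any downsampling; r = 1 is the dense convolution.

The dense atrous convolution (DAC) block runs parallel cascades of 3x3
atrous convolutions built from rates (1, 3, 5) — (1), (3), (1,3) and
(1,3,5), the longer cascades followed by a 1x1 projection — and adds each
branch's output residually onto the input, mixing local and increasingly
global context at unchanged resolution.

The multikernel pooling (MKP) block max-pools the feature map with
windows 2, 3, 5 and 6 (stride = window, ceil mode), squeezes each pooled
map to one channel with a 1x1 convolution, upsamples it back to the input
extents and concatenates the four context channels onto the input.

The bottleneck fusion concatenates the spatial-attention branch with the
DAC -> MKP branch and reduces the stack with a 3x3 convolution back to
the decoder width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import tensor as T
from .blocks import SpatialAttention
from .nn import Conv2d, Module
from .tensor import Tensor


@dataclass
class DilationSpec:
    """Ordered atrous rates used to build the DAC cascades."""

    rates: tuple = (1, 3, 5)

    def validate(self):
        if not self.rates:
            raise ValueError("at least one dilation rate is required")
        if any(int(r) < 1 for r in self.rates):
            raise ValueError("dilation rates must be positive integers")

    def branches(self) -> list[tuple]:
        """Cascade topology derived from the rate list.

        For rates (r1, ..., rn), n >= 2: branches (r1), (r2), (r1, r2),
        ..., (r1, ..., rn).  A single rate yields the one-branch cascade.
        """
        self.validate()
        r = tuple(int(v) for v in self.rates)
        if len(r) == 1:
            return [r]
        return [(r[0],), (r[1],)] + [r[:i] for i in range(2, len(r) + 1)]


@dataclass
class PoolingSpec:
    """Max-pooling window sizes of the MKP pyramid."""

    kernel_sizes: tuple = (2, 3, 5, 6)

    def validate(self):
        if not self.kernel_sizes:
            raise ValueError("at least one pooling kernel is required")
        if any(int(k) < 1 for k in self.kernel_sizes):
            raise ValueError("pooling kernels must be positive integers")


def atrous_conv2d(x, w, b=None, *, rate: int = 1):
    """Size-preserving 2-D atrous convolution.

    ``w`` is (Cout, Cin, k, k) with odd k; zero padding of r(k-1)/2 keeps
    the spatial extents, and rate 1 reduces exactly to the standard dense
    convolution.
    """
    if rate < 1:
        raise ValueError("dilation rate must be >= 1")
    w = T.as_tensor(w)
    k = w.shape[-1]
    if k % 2 == 0:
        raise ValueError("size-preserving atrous convolution needs an odd kernel")
    return T.conv2d(x, w, b, padding=rate * (k - 1) // 2, dilation=rate)


class DACBlock(Module):
    """Dense atrous convolution: parallel cascades summed residually.

    Each cascade applies 3x3 atrous convolutions (ReLU after each) at its
    listed rates; cascades other than the plain rate-1 branch end in a
    1x1 projection.  Channels and spatial extents are preserved.
    """

    def __init__(self, channels: int, spec: DilationSpec | None = None, *,
                 branches: list | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        spec = spec or DilationSpec()
        rng = rng or np.random.default_rng(0)
        self._branch_rates = [tuple(b) for b in (branches or spec.branches())]
        self._max_rate = max(r for br in self._branch_rates for r in br)
        self.branch_convs = []
        self.branch_projs = []
        for rates in self._branch_rates:
            self.branch_convs.append(
                [Conv2d(channels, channels, 3, dilation=r, rng=rng)
                 for r in rates])
            if rates != (1,):
                self.branch_projs.append(Conv2d(channels, channels, 1, rng=rng))
            else:
                self.branch_projs.append(None)

    def forward(self, x):
        x = T.as_tensor(x)
        if min(x.shape[2], x.shape[3]) <= self._max_rate:
            raise ValueError(
                f"spatial extents {x.shape[2:]} too small for dilation rate "
                f"{self._max_rate}")
        out = x
        for convs, proj in zip(self.branch_convs, self.branch_projs):
            h = x
            for conv in convs:
                h = T.relu(conv(h))
            if proj is not None:
                h = T.relu(proj(h))
            out = T.add(out, h)
        return out


class MKPBlock(Module):
    """Multikernel pooling: pyramid of max pools appended as context channels.

    Output channels = input channels + number of pooling kernels.
    Upsampling is nearest-neighbour by default (piecewise constant over
    the pooling cells); bilinear is selectable.
    """

    def __init__(self, channels: int, spec: PoolingSpec | None = None, *,
                 upsample: str = "nearest",
                 rng: np.random.Generator | None = None):
        super().__init__()
        spec = spec or PoolingSpec()
        spec.validate()
        if upsample not in ("nearest", "bilinear"):
            raise ValueError("upsample must be 'nearest' or 'bilinear'")
        rng = rng or np.random.default_rng(0)
        self._kernels = tuple(int(k) for k in spec.kernel_sizes)
        self._upsample = upsample
        self.squeeze = [Conv2d(channels, 1, 1, rng=rng) for _ in self._kernels]

    @property
    def extra_channels(self) -> int:
        return len(self._kernels)

    def forward(self, d):
        d = T.as_tensor(d)
        H, W = d.shape[2], d.shape[3]
        if max(self._kernels) > min(H, W):
            raise ValueError(
                f"pooling kernel {max(self._kernels)} exceeds extents {(H, W)}")
        branches = [d]
        for k, conv in zip(self._kernels, self.squeeze):
            pooled = T.max_pool2d(d, k, ceil_mode=True)
            squeezed = conv(pooled)
            if self._upsample == "nearest":
                up = T.upsample_nearest(squeezed, k, out_hw=(H, W))
            else:
                up = T.resize_bilinear(squeezed, (H, W))
            branches.append(up)
        return T.concat(branches, axis=1)


class BottleneckFusion(Module):
    """Concatenate the spatial-attention and DAC->MKP branches, then reduce.

    With both context modules disabled the fusion degenerates to the
    spatial-attention branch alone (the backbone variant).  ``sum`` mode
    reduces the context branch to the decoder width first and adds it to
    the attention branch; it requires at least one context module.
    """

    def __init__(self, channels: int, *, use_dac: bool = True,
                 use_mkp: bool = True, dilation: DilationSpec | None = None,
                 pooling: PoolingSpec | None = None,
                 fusion_mode: str = "concat", upsample: str = "nearest",
                 rng: np.random.Generator | None = None):
        super().__init__()
        if fusion_mode not in ("concat", "sum"):
            raise ValueError("fusion_mode must be 'concat' or 'sum'")
        if fusion_mode == "sum" and not (use_dac or use_mkp):
            raise ValueError(
                "sum fusion requires at least one of the DAC/MKP branches")
        rng = rng or np.random.default_rng(0)
        self._mode = fusion_mode
        self.attention = SpatialAttention(rng=rng)
        self.dac = DACBlock(channels, dilation, rng=rng) if use_dac else None
        self.mkp = (MKPBlock(channels, pooling, upsample=upsample, rng=rng)
                    if use_mkp else None)
        branch_channels = channels + (self.mkp.extra_channels if use_mkp else 0)
        if fusion_mode == "concat":
            width = channels + (branch_channels if (use_dac or use_mkp) else 0)
        else:
            width = branch_channels
        self.reduce = Conv2d(width, channels, 3, rng=rng)

    def forward(self, f):
        f = T.as_tensor(f)
        sa, att = self.attention(f)
        if self.dac is None and self.mkp is None:
            return self.reduce(sa)
        branch = f
        if self.dac is not None:
            branch = self.dac(branch)
        if self.mkp is not None:
            branch = self.mkp(branch)
        if self._mode == "concat":
            return self.reduce(T.concat([sa, branch], axis=1))
        return T.add(sa, self.reduce(branch))


def dac_block(x, spec: DilationSpec | None = None, *,
              rng: np.random.Generator | None = None):
    """Functional wrapper: run a freshly initialised DAC block."""
    channels = T.as_tensor(x).shape[1]
    return DACBlock(channels, spec, rng=rng)(x)


def mkp_block(d, spec: PoolingSpec | None = None, *,
              rng: np.random.Generator | None = None):
    """Functional wrapper: run a freshly initialised MKP block."""
    channels = T.as_tensor(d).shape[1]
    return MKPBlock(channels, spec, rng=rng)(d)
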