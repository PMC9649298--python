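"""MC-UNet assembly: a four-level U-shaped encoder/decoder whose
bottleneck concatenates a spatial-attention branch with a dense-atrous
-> multikernel-pooling branch.

The encoder halves resolution with 2x2 max pooling at each of the three
skip connections while doubling channel width; the decoder mirrors it
with 2x2 transposed convolutions and skip concatenation, and a final 1x1
convolution + sigmoid emits a per-pixel vessel probability.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from . import tensor as T
from .blocks import ConvBlock, DropBlockConfig, validate_feature_map
from .context import BottleneckFusion, DilationSpec, PoolingSpec
from .nn import Conv2d, ConvTranspose2x2, Module


@dataclass
class ModelConfig:
    """Architectural hyperparameters of MC-UNet.

    depth : number of resolution levels (4 gives three skip connections).
    base_channels : encoder width at full resolution; doubled per level.
    use_dac / use_mkp : enable the bottleneck context modules; with both
        off the bottleneck is the spatial-attention backbone.
    fusion_mode : 'concat' (default) or 'sum' for combining the attention
        and context branches.
    upsample : decoder upsampling, 'transpose' (default) or 'nearest'.
    """

    depth: int = 4
    base_channels: int = 16
    in_channels: int = 3
    dilation_rates: tuple = (1, 3, 5)
    pooling_kernels: tuple = (2, 3, 5, 6)
    use_dac: bool = True
    use_mkp: bool = True
    dropblock: DropBlockConfig = field(default_factory=DropBlockConfig)
    fusion_mode: str = "concat"
    upsample: str = "transpose"
    double_conv: bool = True

    def validate(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 1 or self.in_channels < 1:
            raise ValueError("channel widths must be >= 1")
        if self.fusion_mode not in ("concat", "sum"):
            raise ValueError("fusion_mode must be 'concat' or 'sum'")
        if self.fusion_mode == "sum" and not (self.use_dac or self.use_mkp):
            raise ValueError(
                "sum fusion requested with both context branches disabled")
        if self.upsample not in ("transpose", "nearest"):
            raise ValueError("upsample must be 'transpose' or 'nearest'")
        self.dropblock.validate()
        DilationSpec(tuple(self.dilation_rates)).validate()
        PoolingSpec(tuple(self.pooling_kernels)).validate()

    # -- YAML round trip -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["dilation_rates"] = list(self.dilation_rates)
        d["pooling_kernels"] = list(self.pooling_kernels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "dropblock" in d and isinstance(d["dropblock"], dict):
            d["dropblock"] = DropBlockConfig(**d["dropblock"])
        for key in ("dilation_rates", "pooling_kernels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class MCUNet(Module):
    """The full network; build with :func:`build_model` for a seeded init."""

    def __init__(self, cfg: ModelConfig, *, seed: int = 0):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2**20]))
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([seed, 2**20 + 1]))
        widths = [cfg.base_channels * 2**i for i in range(cfg.depth)]
        n_convs = 2 if cfg.double_conv else 1

        self.encoders = []
        cin = cfg.in_channels
        for w in widths:
            self.encoders.append(ConvBlock(cin, w, cfg.dropblock,
                                           n_convs=n_convs, rng=rng,
                                           dropblock_rng=self._dropout_rng))
            cin = w

        self.fusion = BottleneckFusion(
            widths[-1], use_dac=cfg.use_dac, use_mkp=cfg.use_mkp,
            dilation=DilationSpec(tuple(cfg.dilation_rates)),
            pooling=PoolingSpec(tuple(cfg.pooling_kernels)),
            fusion_mode=cfg.fusion_mode, rng=rng)

        self.upsamples = []
        self.decoders = []
        for w_deep, w_skip in zip(widths[:0:-1], widths[-2::-1]):
            if cfg.upsample == "transpose":
                self.upsamples.append(ConvTranspose2x2(w_deep, w_skip, rng=rng))
            else:
                self.upsamples.append(Conv2d(w_deep, w_skip, 1, rng=rng))
            self.decoders.append(ConvBlock(2 * w_skip, w_skip, cfg.dropblock,
                                           n_convs=n_convs, rng=rng,
                                           dropblock_rng=self._dropout_rng))
        self.head = Conv2d(widths[0], 1, 1, rng=rng)

    # ------------------------------------------------------------------
    @property
    def n_skip_connections(self) -> int:
        return self.cfg.depth - 1

    def _check_input(self, x):
        validate_feature_map(x)
        x = T.as_tensor(x)
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {x.shape[1]}")
        div = 2 ** (self.cfg.depth - 1)
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"spatial extents {x.shape[2:]} must be divisible by {div}; "
                "use predict_image(), which pads and crops")
        return x

    def forward_logits(self, x):
        x = self._check_input(x)
        skips = []
        h = x
        for level, enc in enumerate(self.encoders):
            h = enc(h)
            if level < len(self.encoders) - 1:
                skips.append(h)
                h = T.max_pool2d(h, 2, ceil_mode=False)
        h = self.fusion(h)
        for up, dec, skip in zip(self.upsamples, self.decoders,
                                 reversed(skips)):
            if self.cfg.upsample == "transpose":
                h = up(h)
            else:
                h = up(T.upsample_nearest(h, 2))
            h = dec(T.concat([skip, h], axis=1))
        return self.head(h)

    def forward(self, x):
        """Per-pixel vessel probabilities in (0, 1), same extents as input."""
        return T.sigmoid(self.forward_logits(x))


def build_model(cfg: ModelConfig | None = None, *, seed: int = 0) -> MCUNet:
    """Construct an MC-UNet with a deterministic seeded initialisation."""
    return MCUNet(cfg or ModelConfig(), seed=seed)


def count_parameters(model: Module) -> int:
    """Exact count of learnable scalars (filters, biases, BN affine)."""
    return int(sum(p.data.size for p in model.parameters()))


def build_ablation_suite(cfg: ModelConfig | None = None, *,
                         seed: int = 0) -> list:
    """The four ablation variants sharing all other hyperparameters:
    backbone (spatial attention only), +DAC, +MKP, and the full model."""
    cfg = cfg or ModelConfig()
    variants = [
        ("backbone", replace(cfg, use_dac=False, use_mkp=False)),
        ("+DAC", replace(cfg, use_dac=True, use_mkp=False)),
        ("+MKP", replace(cfg, use_dac=False, use_mkp=True)),
        ("+DAC+MKP", replace(cfg, use_dac=True, use_mkp=True)),
    ]
    return [(name, build_model(c, seed=seed)) for name, c in variants]
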