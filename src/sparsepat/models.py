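"""Network architectures for sparse-view artifact removal.

The full model (MSD-Net) is a U-shaped encoder-decoder operating on
128 x 128 single-channel images:

* encoder: four stages of UIU blocks ("tiny U-Nets" nested inside the
  backbone) each followed by 2x max pooling; the internal depth of a UIU
  block shrinks with its stage resolution so every block bottoms out at an
  8 x 8 feature map;
* bridge: a residual block at 8 x 8;
* decoder: four stages of dilated dense blocks (3x3 kernels at dilations
  1/2/3, i.e. effective receptive fields 3/5/7, densely connected),
  each preceded by bilinear 2x upsampling and encoder skip concatenation;
* head: a full-scale multi-scale connection - every decoder stage plus
  the bridge is reduced to 32 channels, bilinearly upsampled to 128 x 128
  and concatenated into a 160-channel map, fused by a 1x1 convolution and
  squashed through a sigmoid.

Ablation stages reconstruct the progression from a plain U-Net baseline:
``baseline_unet`` (plain double-conv blocks everywhere), ``stage1_uiu``
(UIU encoder), ``stage2_uiu_dense`` (+ dense decoder), ``stage3_full``
(+ multi-scale head).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .nn import autodiff as F
from .nn.autodiff import Tensor
from .nn.modules import (
    BatchNorm2d,
    BilinearUpsample,
    Conv2d,
    ConvBNReLU,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
    Sigmoid,
)

__all__ = [
    "STAGES",
    "ModelConfig",
    "MetricsProfile",
    "UIUBlock",
    "DenseDilatedBlock",
    "ResidualBlock",
    "DoubleConv",
    "MSDNet",
    "build_uiu_block",
    "build_dense_block",
    "build_msdnet",
    "build_stage",
    "profile",
]

STAGES = ("baseline_unet", "stage1_uiu", "stage2_uiu_dense", "stage3_full")

#: deepest feature-map side length inside UIU blocks and at the bridge
BOTTLENECK_SIZE = 8


@dataclass(frozen=True)
class ModelConfig:
    """All architecture hyperparameters.

    The default widths were calibrated so that the full (stage-3) model
    profiles at about 16.01 M trainable parameters and 29.50 G
    multiply-add operations for one 128 x 128 x 1 forward pass; see
    ``docs/methods.md`` for the calibration rationale.
    """

    input_size: int = 128
    in_channels: int = 1
    out_channels: int = 1
    n_levels: int = 4
    encoder_channels: tuple[int, ...] = (88, 128, 136, 264)
    bridge_channels: int = 296
    decoder_channels: tuple[int, ...] = (72, 136, 128, 224)
    head_channels: int = 32
    dilations: tuple[int, ...] = (1, 2, 3)
    uiu_mid_ratio: float = 0.5
    uiu_mid_floor: int = 16
    dense_growth_ratio: float = 1.0
    stage: str = "stage3_full"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        if len(self.encoder_channels) != self.n_levels:
            raise ValueError("encoder_channels must have n_levels entries")
        if len(self.decoder_channels) != self.n_levels:
            raise ValueError("decoder_channels must have n_levels entries")
        size = self.input_size
        if size <= 0 or size & (size - 1):
            raise ValueError("input_size must be a power of two")
        if size // 2**self.n_levels < BOTTLENECK_SIZE:
            raise ValueError("too many levels for the input size")

    @property
    def head_concat_channels(self) -> int:
        return (self.n_levels + 1) * self.head_channels

    def uiu_mid(self, level: int) -> int:
        return max(
            int(round(self.encoder_channels[level] * self.uiu_mid_ratio)),
            self.uiu_mid_floor,
        )

    def dense_growth(self, level: int) -> int:
        return max(int(round(self.decoder_channels[level] * self.dense_growth_ratio)), 8)

    def scaled(self, factor: float) -> "ModelConfig":
        """Width-reduced copy (used for CPU-scale training experiments)."""

        def sc(c: int) -> int:
            return max(int(round(c * factor)), 4)

        return replace(
            self,
            encoder_channels=tuple(sc(c) for c in self.encoder_channels),
            bridge_channels=sc(self.bridge_channels),
            decoder_channels=tuple(sc(c) for c in self.decoder_channels),
            head_channels=sc(self.head_channels),
            uiu_mid_floor=4,
        )


@dataclass(frozen=True)
class MetricsProfile:
    """Trainable parameter count and FLOPs of one forward pass."""

    n_params: int
    flops: float
    macs: float
    convention: str = "mac"  # 1 FLOP = 1 multiply-add ("mac") or "mac2"


class UIUBlock(Module):
    """Nested encoder-decoder ("tiny U-Net") feature extractor.

    The number of internal down/up levels is ``log2(size / 8)`` with a
    minimum of 1, so the deepest internal map is 8 x 8.  For an 8 x 8
    input the single internal level uses dilation-2 convolutions instead
    of pooling (there is no room left to downsample).  The block output is
    the sum of the input projection and the tiny U-Net output (a residual
    connection inside the block).
    """

    def __init__(
        self,
        level_input_size: int,
        in_ch: int,
        out_ch: int,
        mid_ch: int,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        size = level_input_size
        if size <= 0 or size & (size - 1):
            raise ValueError("level_input_size must be a power of two")
        if size < BOTTLENECK_SIZE:
            raise ValueError(f"level_input_size must be >= {BOTTLENECK_SIZE}")
        self.size = size
        self.dilated = size == BOTTLENECK_SIZE
        self.n_internal_levels = max(int(np.log2(size / BOTTLENECK_SIZE)), 1)
        d = self.n_internal_levels
        self.conv_in = ConvBNReLU(in_ch, out_ch, rng)
        self.pool = MaxPool2d()
        enc = [ConvBNReLU(out_ch, mid_ch, rng)]
        for _ in range(d - 1):
            enc.append(ConvBNReLU(mid_ch, mid_ch, rng))
        self.enc = enc
        self.bottom = ConvBNReLU(mid_ch, mid_ch, rng, dilation=2 if self.dilated else 1)
        dec = []
        for i in range(d - 1):
            dec.append(ConvBNReLU(2 * mid_ch, mid_ch, rng))
        dec.append(ConvBNReLU(2 * mid_ch, out_ch, rng))
        self.dec = dec

    def forward(self, x: Tensor) -> Tensor:
        x0 = self.conv_in(x)
        feats = [self.enc[0](x0)]
        for layer in self.enc[1:]:
            feats.append(layer(self.pool(feats[-1])))
        if self.dilated:
            u = self.bottom(feats[-1])
        else:
            u = self.bottom(self.pool(feats[-1]))
        for layer, skip in zip(self.dec, reversed(feats)):
            if u.shape[2] != skip.shape[2]:
                u = F.bilinear_resize(u, (skip.shape[2], skip.shape[3]))
            u = layer(F.concat([u, skip], axis=1))
        return F.add(x0, u)


class DenseDilatedBlock(Module):
    """Densely connected multi-dilation convolutions.

    One branch per dilation rate (default 1/2/3 -> effective receptive
    fields 3x3/5x5/7x7 from 3x3 kernels); each branch is two
    conv-BN-ReLU layers and receives the concatenation of the block input
    and all previous branch outputs.  A 1x1 fusion convolution maps the
    full concatenation to ``out_ch``.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        growth: int,
        rng: np.random.Generator,
        dilations: tuple[int, ...] = (1, 2, 3),
    ) -> None:
        super().__init__()
        if not dilations:
            raise ValueError("dilations must be nonempty")
        self.dilations = tuple(dilations)
        branches = []
        ch = in_ch
        for dil in self.dilations:
            branches.append(
                Sequential(
                    ConvBNReLU(ch, growth, rng, dilation=dil),
                    ConvBNReLU(growth, growth, rng, dilation=dil),
                )
            )
            ch += growth
        self.branches = branches
        self.fuse = ConvBNReLU(ch, out_ch, rng, kernel_size=1)

    def forward(self, x: Tensor) -> Tensor:
        feats = [x]
        for branch in self.branches:
            inp = feats[0] if len(feats) == 1 else F.concat(feats, axis=1)
            feats.append(branch(inp))
        return self.fuse(F.concat(feats, axis=1))


class ResidualBlock(Module):
    """Two 3x3 convolutions with an identity shortcut (1x1 projection when
    the widths differ)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.conv1 = ConvBNReLU(in_ch, out_ch, rng)
        self.conv2 = Sequential(Conv2d(out_ch, out_ch, 3, rng=rng), BatchNorm2d(out_ch))
        if in_ch != out_ch:
            self.shortcut = Sequential(
                Conv2d(in_ch, out_ch, 1, rng=rng), BatchNorm2d(out_ch)
            )
        else:
            self.shortcut = None
        self.act = ReLU()

    def forward(self, x: Tensor) -> Tensor:
        identity = self.shortcut(x) if self.shortcut is not None else x
        return self.act(F.add(self.conv2(self.conv1(x)), identity))


class DoubleConv(Module):
    """Plain U-Net stage: two conv-BN-ReLU layers."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.block = Sequential(ConvBNReLU(in_ch, out_ch, rng), ConvBNReLU(out_ch, out_ch, rng))

    def forward(self, x: Tensor) -> Tensor:
        return self.block(x)


class MSDNet(Module):
    """Configurable backbone covering all ablation stages (see module
    docstring).  ``forward`` maps (N, 1, 128, 128) to (N, 1, 128, 128)
    with outputs in (0, 1)."""

    def __init__(self, cfg: ModelConfig) -> None:
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        enc_ch = cfg.encoder_channels
        dec_ch = cfg.decoder_channels
        use_uiu = cfg.stage != "baseline_unet"
        use_dense = cfg.stage in ("stage2_uiu_dense", "stage3_full")
        self.use_head = cfg.stage == "stage3_full"

        self.pool = MaxPool2d()
        sizes = [cfg.input_size // 2**i for i in range(cfg.n_levels)]
        self.level_sizes = sizes
        encoder = []
        ch = cfg.in_channels
        for lvl in range(cfg.n_levels):
            if use_uiu:
                encoder.append(
                    UIUBlock(sizes[lvl], ch, enc_ch[lvl], cfg.uiu_mid(lvl), rng)
                )
            else:
                encoder.append(DoubleConv(ch, enc_ch[lvl], rng))
            ch = enc_ch[lvl]
        self.encoder = encoder
        self.bridge = ResidualBlock(enc_ch[-1], cfg.bridge_channels, rng)
        decoder = []
        ch = cfg.bridge_channels
        for lvl in reversed(range(cfg.n_levels)):
            in_ch = ch + enc_ch[lvl]
            if use_dense:
                decoder.append(
                    DenseDilatedBlock(
                        in_ch, dec_ch[lvl], cfg.dense_growth(lvl), rng, cfg.dilations
                    )
                )
            else:
                decoder.append(DoubleConv(in_ch, dec_ch[lvl], rng))
            ch = dec_ch[lvl]
        self.decoder = decoder  # deepest level first
        self.up = BilinearUpsample(scale=2)

        if self.use_head:
            hc = cfg.head_channels
            branch_src = list(dec_ch) + [cfg.bridge_channels]
            self.head_branches = [
                ConvBNReLU(src, hc, rng) for src in branch_src
            ]
            self.head_fuse = Conv2d(
                cfg.head_concat_channels, cfg.out_channels, 1, bias=True, rng=rng
            )
        else:
            self.head_fuse = Conv2d(dec_ch[0], cfg.out_channels, 1, bias=True, rng=rng)
        self.act = Sigmoid()
        #: channel width of the concatenated multi-scale map seen by the
        #: last forward pass (None before any forward / without the head)
        self.last_head_width: int | None = None

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        skips = []
        h = x
        for lvl, block in enumerate(self.encoder):
            if lvl > 0:
                h = self.pool(h)
            h = block(h)
            skips.append(h)
        b = self.bridge(self.pool(h))
        h = b
        dec_feats: list[Tensor] = []
        for block, skip in zip(self.decoder, reversed(skips)):
            h = block(F.concat([self.up(h), skip], axis=1))
            dec_feats.append(h)
        if self.use_head:
            full = (self.cfg.input_size, self.cfg.input_size)
            branches = []
            for feat, conv in zip(dec_feats[::-1] + [b], self.head_branches):
                z = conv(feat)
                if z.shape[2:] != full:
                    z = F.bilinear_resize(z, full)
                branches.append(z)
            # order: full-resolution decoder map first, then deeper stages
            fused = F.concat(branches, axis=1)
            self.last_head_width = fused.shape[1]
            out = self.head_fuse(fused)
        else:
            out = self.head_fuse(dec_feats[-1])
        return self.act(out)


# ---------------------------------------------------------------------------
# builders mirroring the pipeline vocabulary


def build_uiu_block(
    level_input_size: int,
    in_ch: int,
    out_ch: int,
    mid_ch: int | None = None,
    rng: np.random.Generator | None = None,
) -> UIUBlock:
    rng = rng or np.random.default_rng(0)
    mid_ch = mid_ch or max(out_ch // 2, 16)
    return UIUBlock(level_input_size, in_ch, out_ch, mid_ch, rng)


def build_dense_block(
    in_ch: int,
    out_ch: int,
    dilations: tuple[int, ...] = (1, 2, 3),
    growth: int | None = None,
    rng: np.random.Generator | None = None,
) -> DenseDilatedBlock:
    rng = rng or np.random.default_rng(0)
    growth = growth or out_ch
    return DenseDilatedBlock(in_ch, out_ch, growth, rng, dilations)


def build_msdnet(cfg: ModelConfig | None = None) -> MSDNet:
    cfg = cfg or ModelConfig()
    if cfg.stage != "stage3_full":
        cfg = replace(cfg, stage="stage3_full")
    return MSDNet(cfg)


def build_stage(cfg: ModelConfig | None, stage: str) -> MSDNet:
    cfg = cfg or ModelConfig()
    return MSDNet(replace(cfg, stage=stage))


# ---------------------------------------------------------------------------
# profiling


def profile(
    model: MSDNet, input_size: int | None = None, convention: str = "mac"
) -> MetricsProfile:
    """Exact trainable-parameter count plus conv multiply-add count.

    The spatial extent of every convolution is observed by pushing an
    empty (batch-0) probe through the network in eval mode, so the count
    follows the actual dataflow.  ``convention="mac"`` counts one fused
    multiply-add as one FLOP (the convention under which the model's
    reference footprint is quoted); ``"mac2"`` doubles it.
    """
    if convention not in ("mac", "mac2"):
        raise ValueError("convention must be 'mac' or 'mac2'")
    size = input_size or model.cfg.input_size
    was_training = model.training
    model.eval()
    convs = [m for m in model.modules() if isinstance(m, Conv2d)]
    for conv in convs:
        conv._probe_hw = None
    probe = Tensor(np.zeros((0, model.cfg.in_channels, size, size), dtype=np.float32))
    orig_forward = Conv2d.forward

    def recording_forward(self, x):
        self._probe_hw = (x.shape[2], x.shape[3])
        return orig_forward(self, x)

    Conv2d.forward = recording_forward
    try:
        model(probe)
    finally:
        Conv2d.forward = orig_forward
        model.train(was_training)
    macs = 0.0
    for conv in convs:
        if conv._probe_hw is None:
            continue
        h, w = conv._probe_hw
        macs += h * w * conv.out_ch * conv.in_ch * conv.kernel_size**2
        if conv.bias is not None:
            macs += h * w * conv.out_ch
    flops = macs * (2.0 if convention == "mac2" else 1.0)
    return MetricsProfile(model.n_parameters(), flops, macs, convention)
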