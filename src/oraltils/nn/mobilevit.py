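"""Hybrid convolution/transformer encoder (MobileViT-style).

The encoder interleaves inverted-residual convolution blocks with
transformer blocks that attend across non-overlapping 2x2 patch positions,
capturing local texture and long-range context at a small parameter budget.
It emits one feature map per downsampling stage (strides 2, 4, 8, 16, 32)
so a U-shaped decoder can attach skip connections.

Width presets trade fidelity for desk-scale runtime; ``"xs"`` mirrors the
published extra-small configuration, ``"tiny"``/``"micro"`` are reduced
variants used for CPU-scale experiments and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .layers import (
    BatchNorm2d,
    Conv2d,
    DepthwiseConv2d,
    Module,
    Sequential,
    SiLU,
    TransformerBlock,
    concatenate,
)
from .tensor import Tensor

__all__ = ["EncoderPreset", "ENCODER_PRESETS", "MobileViTEncoder"]


@dataclass(frozen=True)
class EncoderPreset:
    stem: int
    stage_channels: tuple[int, int, int, int]
    vit_dims: tuple[int, int, int]
    vit_depths: tuple[int, int, int] = (2, 2, 2)
    heads: int = 4
    expansion: int = 4
    mlp_ratio: float = 2.0


ENCODER_PRESETS: dict[str, EncoderPreset] = {
    # close to the published extra-small width schedule
    "xs": EncoderPreset(16, (48, 64, 80, 96), (96, 120, 144), (2, 4, 3), 4, 4),
    "s": EncoderPreset(16, (64, 96, 128, 160), (144, 192, 240), (2, 4, 3), 4, 4),
    # desk-scale variants
    "tiny": EncoderPreset(8, (16, 24, 32, 48), (32, 48, 64), (1, 1, 1), 2, 2),
    "micro": EncoderPreset(8, (12, 16, 24, 32), (24, 32, 40), (1, 1, 1), 2, 2),
}


class ConvBNAct(Module):
    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1, act: bool = True):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, k, stride=stride, padding=k // 2, bias=False)
        self.bn = BatchNorm2d(c_out)
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn(self.conv(x))
        return y.silu() if self.act else y


class InvertedResidual(Module):
    """MobileNetV2 block: expand 1x1 -> depthwise 3x3 -> project 1x1."""

    def __init__(self, c_in: int, c_out: int, stride: int, expansion: int):
        super().__init__()
        hidden = c_in * expansion
        self.use_res = stride == 1 and c_in == c_out
        self.expand = ConvBNAct(c_in, hidden, k=1)
        self.dw = DepthwiseConv2d(hidden, 3, stride=stride, padding=1, bias=False)
        self.dw_bn = BatchNorm2d(hidden)
        self.project = ConvBNAct(hidden, c_out, k=1, act=False)

    def forward(self, x: Tensor) -> Tensor:
        y = self.expand(x)
        y = self.dw_bn(self.dw(y)).silu()
        y = self.project(y)
        return x + y if self.use_res else y


class MobileViTBlock(Module):
    """Local conv features + transformer over unfolded patch positions.

    The map is split into non-overlapping ``patch x patch`` cells; pixels at
    the same offset within each cell form a sequence processed by the
    transformer (global mixing), then the map is folded back, projected and
    fused with the input through a 3x3 convolution.  The patch size shrinks
    to 1 when the map is too small or odd-sized, which keeps the block valid
    at bottleneck resolutions.
    """

    def __init__(self, ch: int, dim: int, depth: int, heads: int,
                 patch: int = 2, mlp_ratio: float = 2.0):
        super().__init__()
        self.patch = patch
        self.local = ConvBNAct(ch, ch, k=3)
        self.to_dim = Conv2d(ch, dim, 1, bias=False)
        self.blocks = [TransformerBlock(dim, heads, mlp_ratio) for _ in range(depth)]
        self.to_ch = ConvBNAct(dim, ch, k=1)
        self.fuse = ConvBNAct(2 * ch, ch, k=3)

    def forward(self, x: Tensor) -> Tensor:
        n, _, h, w = x.shape
        y = self.to_dim(self.local(x))
        d = y.shape[1]
        p = self.patch if (h % self.patch == 0 and w % self.patch == 0 and h >= self.patch) else 1
        # (N, D, H, W) -> (N * p * p, (H/p) * (W/p), D)
        y = y.reshape(n, d, h // p, p, w // p, p)
        y = y.transpose(0, 3, 5, 2, 4, 1).reshape(n * p * p, (h // p) * (w // p), d)
        for blk in self.blocks:
            y = blk(y)
        y = y.reshape(n, p, p, h // p, w // p, d).transpose(0, 5, 3, 1, 4, 2)
        y = y.reshape(n, d, h, w)
        y = self.to_ch(y)
        return self.fuse(concatenate([x, y], axis=1))


class MobileViTEncoder(Module):
    """Five-stage encoder; ``forward`` returns [s1..s5] at strides 2..32."""

    def __init__(self, variant: str = "xs"):
        super().__init__()
        if variant not in ENCODER_PRESETS:
            raise ValueError(f"unknown encoder variant {variant!r}")
        p = ENCODER_PRESETS[variant]
        self.preset = p
        c1, c2, c3, c4 = p.stage_channels
        self.stem = ConvBNAct(3, p.stem, k=3, stride=2)
        self.stage1 = Sequential(
            InvertedResidual(p.stem, c1, 2, p.expansion),
            InvertedResidual(c1, c1, 1, p.expansion),
        )
        self.stage2 = Sequential(
            InvertedResidual(c1, c2, 2, p.expansion),
            MobileViTBlock(c2, p.vit_dims[0], p.vit_depths[0], p.heads, mlp_ratio=p.mlp_ratio),
        )
        self.stage3 = Sequential(
            InvertedResidual(c2, c3, 2, p.expansion),
            MobileViTBlock(c3, p.vit_dims[1], p.vit_depths[1], p.heads, mlp_ratio=p.mlp_ratio),
        )
        self.stage4 = Sequential(
            InvertedResidual(c3, c4, 2, p.expansion),
            MobileViTBlock(c4, p.vit_dims[2], p.vit_depths[2], p.heads, mlp_ratio=p.mlp_ratio),
        )

    @property
    def feature_channels(self) -> tuple[int, int, int, int, int]:
        p = self.preset
        return (p.stem, *p.stage_channels)

    @property
    def downsampling(self) -> int:
        return 32

    def forward(self, x: Tensor) -> list[Tensor]:
        s1 = self.stem(x)
        s2 = self.stage1(s1)
        s3 = self.stage2(s2)
        s4 = self.stage3(s3)
        s5 = self.stage4(s4)
        return [s1, s2, s3, s4, s5]
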