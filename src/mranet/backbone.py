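"""Multiscale feature-pyramid backbones.

Two interchangeable variants produce the four-level pyramid ``f1..f4`` at
strides 4/8/16/32 relative to the input:

* ``pvtv2_b2`` — a Pyramid Vision Transformer v2 (B2 configuration: depths
  3/4/6/3, dims 64/128/320/512, heads 1/2/5/8, spatial-reduction ratios
  8/4/2/1, overlapping patch embeddings, depthwise-conv MLPs). ImageNet
  weights may optionally be loaded from a user-supplied checkpoint file; all
  tests run from seeded random initialisation.
* ``tiny_conv`` — a small strided-convolution pyramid honouring the same
  output contract, for CPU-scale tests and experiments.

Input sizes must be multiples of 32 so every stride divides exactly; other
sizes are rejected rather than silently padded, which would desynchronise
image and mask geometry.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import (BatchNorm2d, Conv2d, LayerNorm, Linear, Module,
                     ModuleList, Sequential)

__all__ = [
    "BackboneConfig",
    "BackboneFeatures",
    "make_backbone",
    "extract_pyramid",
    "TinyConvBackbone",
    "PVTv2Backbone",
]

STAGE_STRIDES = (4, 8, 16, 32)


class ConfigurationError(ValueError):
    """Raised for invalid architecture or runtime configuration."""


class DimensionError(ValueError):
    """Raised when tensor geometry violates a contract."""


@dataclass
class BackboneConfig:
    variant: str = "pvtv2_b2"
    stage_channels: tuple[int, int, int, int] = (64, 128, 320, 512)
    stage_strides: tuple[int, int, int, int] = STAGE_STRIDES
    input_size: tuple[int, int] = (352, 352)
    pretrained_path: str | None = None
    # pvtv2 hyperparameters (ignored by tiny_conv)
    depths: tuple[int, int, int, int] = (3, 4, 6, 3)
    num_heads: tuple[int, int, int, int] = (1, 2, 5, 8)
    mlp_ratios: tuple[int, int, int, int] = (8, 8, 4, 4)
    sr_ratios: tuple[int, int, int, int] = (8, 4, 2, 1)

    def __post_init__(self):
        if self.variant not in ("pvtv2_b2", "tiny_conv"):
            raise ConfigurationError(
                f"unknown backbone variant {self.variant!r}; "
                "expected 'pvtv2_b2' or 'tiny_conv'")
        if len(self.stage_channels) != 4 or any(c <= 0 for c in self.stage_channels):
            raise ConfigurationError("stage_channels must be 4 positive integers")
        strides = tuple(self.stage_strides)
        if strides != STAGE_STRIDES:
            # contract: strictly increasing, each dividing the next; the
            # architecture is built for the canonical 4/8/16/32 ladder.
            raise ConfigurationError(
                f"stage_strides fixed at {STAGE_STRIDES}, got {strides}")
        h, w = self.input_size
        if h % 32 or w % 32 or h <= 0 or w <= 0:
            raise ConfigurationError(
                f"input_size must be positive multiples of 32, got {self.input_size}")
        if self.pretrained_path is not None and not os.path.isfile(self.pretrained_path):
            raise ConfigurationError(
                f"pretrained weight file not found: {self.pretrained_path}")


@dataclass
class BackboneFeatures:
    """The four-level pyramid f1..f4 (channels-first Tensors)."""

    f1: Tensor
    f2: Tensor
    f3: Tensor
    f4: Tensor

    def levels(self) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        return (self.f1, self.f2, self.f3, self.f4)


def _cbr(cin: int, cout: int, k: int = 3, stride: int = 1) -> Sequential:
    return Sequential(
        Conv2d(cin, cout, k, stride=stride, padding=k // 2),
        BatchNorm2d(cout),
        _ReLU(),
    )


class _ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class TinyConvBackbone(Module):
    """Strided-convolution pyramid: cheap stand-in honouring the contract."""

    def __init__(self, config: BackboneConfig):
        super().__init__()
        self.config = config
        c1, c2, c3, c4 = config.stage_channels
        self.stem = Sequential(_cbr(3, c1, stride=2), _cbr(c1, c1, stride=2))
        self.stage2 = _cbr(c1, c2, stride=2)
        self.stage3 = _cbr(c2, c3, stride=2)
        self.stage4 = _cbr(c3, c4, stride=2)

    def forward(self, x: Tensor) -> BackboneFeatures:
        f1 = self.stem(x)
        f2 = self.stage2(f1)
        f3 = self.stage3(f2)
        f4 = self.stage4(f3)
        return BackboneFeatures(f1, f2, f3, f4)


# ---------------------------------------------------------------------------
# PVTv2
# ---------------------------------------------------------------------------

class _OverlapPatchEmbed(Module):
    def __init__(self, cin: int, cout: int, patch: int, stride: int):
        super().__init__()
        self.proj = Conv2d(cin, cout, patch, stride=stride, padding=patch // 2)
        self.norm = LayerNorm(cout)

    def forward(self, x: Tensor) -> tuple[Tensor, int, int]:
        x = self.proj(x)
        n, c, h, w = x.shape
        tokens = x.reshape((n, c, h * w)).transpose((0, 2, 1))
        return self.norm(tokens), h, w


class _SpatialReductionAttention(Module):
    def __init__(self, dim: int, heads: int, sr_ratio: int):
        super().__init__()
        if dim % heads:
            raise ConfigurationError(f"dim {dim} not divisible by heads {heads}")
        self.dim = dim
        self.heads = heads
        self.head_dim = dim // heads
        self.scale = self.head_dim ** -0.5
        self.sr_ratio = sr_ratio
        self.q = Linear(dim, dim)
        self.kv = Linear(dim, dim * 2)
        self.proj = Linear(dim, dim)
        if sr_ratio > 1:
            self.sr = Conv2d(dim, dim, sr_ratio, stride=sr_ratio, padding=0)
            self.sr_norm = LayerNorm(dim)

    def forward(self, x: Tensor, h: int, w: int) -> Tensor:
        n, l, c = x.shape
        q = self.q(x).reshape((n, l, self.heads, self.head_dim)).transpose((0, 2, 1, 3))
        if self.sr_ratio > 1:
            xm = x.transpose((0, 2, 1)).reshape((n, c, h, w))
            xr = self.sr(xm)
            lr = xr.shape[2] * xr.shape[3]
            xr = xr.reshape((n, c, lr)).transpose((0, 2, 1))
            kv_in = self.sr_norm(xr)
        else:
            kv_in = x
            lr = l
        kv = self.kv(kv_in).reshape((n, lr, 2, self.heads, self.head_dim))
        kv = kv.transpose((2, 0, 3, 1, 4))
        k, v = kv[0], kv[1]
        attn = ad.matmul(q, k.transpose((0, 1, 3, 2))) * self.scale
        attn = ad.softmax(attn, axis=-1)
        out = ad.matmul(attn, v)
        out = out.transpose((0, 2, 1, 3)).reshape((n, l, c))
        return self.proj(out)


class _DWConvMLP(Module):
    def __init__(self, dim: int, hidden: int):
        super().__init__()
        self.fc1 = Linear(dim, hidden)
        self.dw = Conv2d(hidden, hidden, 3, padding=1, groups=hidden)
        self.fc2 = Linear(hidden, dim)
        self.hidden = hidden

    def forward(self, x: Tensor, h: int, w: int) -> Tensor:
        n, l, _ = x.shape
        x = self.fc1(x)
        xm = x.transpose((0, 2, 1)).reshape((n, self.hidden, h, w))
        xm = self.dw(xm)
        x = xm.reshape((n, self.hidden, l)).transpose((0, 2, 1))
        return self.fc2(ad.gelu(x))


class _TransformerBlock(Module):
    def __init__(self, dim: int, heads: int, mlp_ratio: int, sr_ratio: int):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = _SpatialReductionAttention(dim, heads, sr_ratio)
        self.norm2 = LayerNorm(dim)
        self.mlp = _DWConvMLP(dim, dim * mlp_ratio)

    def forward(self, x: Tensor, h: int, w: int) -> Tensor:
        x = x + self.attn(self.norm1(x), h, w)
        x = x + self.mlp(self.norm2(x), h, w)
        return x


class PVTv2Backbone(Module):
    """Pyramid Vision Transformer v2 feature extractor (no classifier head)."""

    def __init__(self, config: BackboneConfig):
        super().__init__()
        self.config = config
        dims = config.stage_channels
        self.embeds = ModuleList()
        self.stages = ModuleList()
        self.norms = ModuleList()
        cin = 3
        for i in range(4):
            patch, stride = (7, 4) if i == 0 else (3, 2)
            self.embeds.append(_OverlapPatchEmbed(cin, dims[i], patch, stride))
            blocks = ModuleList(
                _TransformerBlock(dims[i], config.num_heads[i],
                                  config.mlp_ratios[i], config.sr_ratios[i])
                for _ in range(config.depths[i]))
            self.stages.append(blocks)
            self.norms.append(LayerNorm(dims[i]))
            cin = dims[i]

    def forward(self, x: Tensor) -> BackboneFeatures:
        feats = []
        for embed, blocks, norm in zip(self.embeds, self.stages, self.norms):
            tokens, h, w = embed(x)
            for block in blocks:
                tokens = block(tokens, h, w)
            tokens = norm(tokens)
            n = tokens.shape[0]
            x = tokens.transpose((0, 2, 1)).reshape((n, -1, h, w))
            feats.append(x)
        return BackboneFeatures(*feats)


def make_backbone(config: BackboneConfig) -> Module:
    """Build a feature extractor honouring the pyramid contract."""
    if config.variant == "tiny_conv":
        backbone: Module = TinyConvBackbone(config)
    else:
        backbone = PVTv2Backbone(config)
    if config.pretrained_path is not None:
        _load_weights(backbone, config.pretrained_path)
    return backbone


def _load_weights(backbone: Module, path: str) -> None:
    with np.load(path) as archive:
        state = {k: archive[k] for k in archive.files}
    params = dict(backbone.named_parameters())
    for key, value in state.items():
        if key.startswith("buffer:"):
            continue
        if key not in params:
            raise ValueError(f"weight file contains unknown parameter {key!r}")
        if params[key].data.shape != value.shape:
            raise ValueError(
                f"shape mismatch while loading {key!r}: model expects "
                f"{params[key].data.shape}, file has {value.shape}")
    backbone.load_state_dict(state)


def extract_pyramid(backbone: Module, images) -> BackboneFeatures:
    """Run the backbone on an N x 3 x H x W batch; enforce geometry contracts."""
    x = ad.astensor(images)
    if x.ndim != 4 or x.shape[1] != 3:
        raise DimensionError(f"expected images of shape (N, 3, H, W), got {x.shape}")
    n, _, h, w = x.shape
    if n < 1:
        raise DimensionError("batch must contain at least one image")
    if h % 32 or w % 32:
        raise DimensionError(
            f"input height and width must be multiples of 32 (got {h}x{w}); "
            "inputs are rejected rather than padded")
    feats = backbone(x)
    for i, f in enumerate(feats.levels(), start=1):
        stride = STAGE_STRIDES[i - 1]
        expect = (h // stride, w // stride)
        if f.shape[2:] != expect:
            raise DimensionError(
                f"f{i} spatial size {f.shape[2:]} != input/{stride} {expect}")
        if not np.all(np.isfinite(f.data)):
            raise FloatingPointError(f"non-finite values in backbone level f{i}")
    return feats
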