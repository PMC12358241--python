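"""Encoder feature enhancement: residual self-attention and multi-kernel
dilated convolution refinement of the backbone pyramid.

The top pyramid level f4 is refined by a residual self-attention block (RSAB):
query/key/value maps come from 1x1 convolutions, queries and keys at a reduced
channel width, attention is a dense softmax over key positions, and the
attended values are projected and added back to f4. The three lower levels
f1..f3 pass through CMKD: four parallel convolution branches with kernel sizes
1/3/7/11, concatenation, four parallel 3x3 dilated branches at rates 1/3/7/11,
a 1x1 fusion back to the input width, a 1x1-conv + batch-norm residual
shortcut, and finally a channel-then-spatial attention refinement added on
top. A CBR projection then maps every refined level to the common decoder
width D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .backbone import (BackboneFeatures, ConfigurationError, DimensionError)
from .layers import BatchNorm2d, Conv2d, Identity, Module, ModuleList, Sequential

__all__ = [
    "RSABParams",
    "CMKDParams",
    "EnhancedFeatures",
    "ResidualSelfAttention",
    "CMKD",
    "ChannelAttention",
    "SpatialAttention",
    "CBR",
    "EncoderEnhancer",
]


@dataclass
class RSABParams:
    channels: int
    qk_reduction: int = 8

    def __post_init__(self):
        if self.channels <= 0 or self.qk_reduction <= 0:
            raise ConfigurationError("RSAB channels and qk_reduction must be positive")
        if self.channels % self.qk_reduction:
            raise ConfigurationError(
                f"RSAB channels ({self.channels}) must be divisible by "
                f"qk_reduction ({self.qk_reduction})")


@dataclass
class CMKDParams:
    in_channels: int
    branch_width: int | None = None  # default round(C / 2)
    kernel_sizes: tuple[int, ...] = (1, 3, 7, 11)
    dilation_rates: tuple[int, ...] = (1, 3, 7, 11)
    attention_reduction: int = 16
    spatial_kernel: int = 7

    def __post_init__(self):
        if self.in_channels <= 0:
            raise ConfigurationError("CMKD in_channels must be positive")
        if self.branch_width is None:
            self.branch_width = max(1, round(self.in_channels / 2))
        if self.branch_width < 1:
            raise ConfigurationError("CMKD branch_width must be >= 1")
        for k in self.kernel_sizes:
            if k % 2 == 0:
                raise ConfigurationError(f"CMKD kernel sizes must be odd, got {k}")
        if self.spatial_kernel % 2 == 0:
            raise ConfigurationError(
                f"spatial attention kernel must be odd, got {self.spatial_kernel}")
        if self.in_channels % self.attention_reduction:
            raise ConfigurationError(
                f"in_channels ({self.in_channels}) must be divisible by "
                f"attention_reduction ({self.attention_reduction})")


class _ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class CBR(Sequential):
    """Convolution -> batch normalisation -> ReLU."""

    def __init__(self, cin: int, cout: int, kernel_size: int = 3):
        super().__init__(
            Conv2d(cin, cout, kernel_size, padding=kernel_size // 2),
            BatchNorm2d(cout),
            _ReLU(),
        )


class ResidualSelfAttention(Module):
    """Dense spatial self-attention with an additive skip (RSAB).

    q and k are channel-reduced 1x1 projections; the attention matrix is the
    softmax over key positions of the query-key inner products; v keeps the
    full channel width; the attended values are reshaped back to a map,
    passed through a 1x1 output convolution and added to the input.
    """

    def __init__(self, params: RSABParams):
        super().__init__()
        self.params = params
        c = params.channels
        cr = c // params.qk_reduction
        self.query = Conv2d(c, cr, 1)
        self.key = Conv2d(c, cr, 1)
        self.value = Conv2d(c, c, 1)
        self.out = Conv2d(c, c, 1)

    def attention_matrix(self, f4: Tensor) -> Tensor:
        """The (N, L, L) row-stochastic attention over key positions."""
        n, c, h, w = f4.shape
        l = h * w
        q = self.query(f4).reshape((n, -1, l)).transpose((0, 2, 1))  # (N, L, Cr)
        k = self.key(f4).reshape((n, -1, l))                          # (N, Cr, L)
        return ad.softmax(ad.matmul(q, k), axis=-1)

    def forward(self, f4: Tensor) -> Tensor:
        if f4.shape[1] != self.params.channels:
            raise DimensionError(
                f"RSAB expected {self.params.channels} channels, got {f4.shape[1]}")
        n, c, h, w = f4.shape
        l = h * w
        attn = self.attention_matrix(f4)
        v = self.value(f4).reshape((n, c, l))
        attended = ad.matmul(v, attn.transpose((0, 2, 1)))  # (N, C, L)
        attended = attended.reshape((n, c, h, w))
        return f4 + self.out(attended)


class ChannelAttention(Module):
    """Per-channel sigmoid gates from pooled descriptors (CBAM channel arm)."""

    def __init__(self, channels: int, reduction: int = 16):
        super().__init__()
        if channels % reduction:
            raise ConfigurationError(
                f"channels ({channels}) must be divisible by reduction ({reduction})")
        hidden = channels // reduction
        self.fc1 = Conv2d(channels, hidden, 1)
        self.fc2 = Conv2d(hidden, channels, 1)

    def gates(self, f: Tensor) -> Tensor:
        avg = f.mean(axis=(2, 3), keepdims=True)
        mx = f.max(axis=(2, 3), keepdims=True)
        bottleneck = lambda d: self.fc2(ad.relu(self.fc1(d)))
        return ad.sigmoid(bottleneck(avg) + bottleneck(mx))

    def forward(self, f: Tensor) -> Tensor:
        return f * self.gates(f)


class SpatialAttention(Module):
    """One-channel spatial sigmoid gate from channel mean/max maps."""

    def __init__(self, kernel_size: int = 7):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ConfigurationError(
                f"spatial attention kernel must be odd, got {kernel_size}")
        self.conv = Conv2d(2, 1, kernel_size, padding=kernel_size // 2)

    def gates(self, f: Tensor) -> Tensor:
        mean_map = f.mean(axis=1, keepdims=True)
        max_map = f.max(axis=1, keepdims=True)
        return ad.sigmoid(self.conv(ad.concat([mean_map, max_map], axis=1)))

    def forward(self, f: Tensor) -> Tensor:
        return f * self.gates(f)


class CMKD(Module):
    """Multi-kernel + multi-dilation convolution block with residual shortcut
    and channel/spatial attention refinement."""

    def __init__(self, params: CMKDParams):
        super().__init__()
        self.params = params
        c, b = params.in_channels, params.branch_width
        self.kernel_branches = ModuleList(
            CBR(c, b, k) for k in params.kernel_sizes)
        nb = len(params.kernel_sizes)
        self.dilated_branches = ModuleList()
        for r in params.dilation_rates:
            self.dilated_branches.append(Sequential(
                Conv2d(nb * b, b, 3, padding=r, dilation=r),
                BatchNorm2d(b),
                _ReLU(),
            ))
        nd = len(params.dilation_rates)
        self.fuse = Conv2d(nd * b, c, 1)
        self.shortcut = Sequential(Conv2d(c, c, 1), BatchNorm2d(c))
        self.channel_attention = ChannelAttention(c, params.attention_reduction)
        self.spatial_attention = SpatialAttention(params.spatial_kernel)

    def main_branch(self, fi: Tensor) -> Tensor:
        """Kernel branches -> concat -> dilated branches -> concat -> 1x1 fuse."""
        fcon = ad.concat([branch(fi) for branch in self.kernel_branches], axis=1)
        fdil = ad.concat([branch(fcon) for branch in self.dilated_branches], axis=1)
        return self.fuse(fdil)

    def pre_attention(self, fi: Tensor) -> Tensor:
        """ReLU(main + shortcut): the refined map before attention."""
        return ad.relu(self.main_branch(fi) + self.shortcut(fi))

    def forward(self, fi: Tensor) -> Tensor:
        if fi.shape[1] != self.params.in_channels:
            raise DimensionError(
                f"CMKD expected {self.params.in_channels} channels, "
                f"got {fi.shape[1]}")
        fmain = self.pre_attention(fi)
        return fmain + self.spatial_attention(self.channel_attention(fmain))


@dataclass
class EnhancedFeatures:
    """Refined maps f' and decoder-width projections f'' for all four levels."""

    fprime: tuple[Tensor, Tensor, Tensor, Tensor]
    fdp: tuple[Tensor, Tensor, Tensor, Tensor]


class EncoderEnhancer(Module):
    """Route f1..f3 through CMKD and f4 through RSAB, then CBR-project all
    levels to the common decoder width D. Either refinement can be ablated,
    in which case the identity is substituted and CBR applies directly."""

    def __init__(self, stage_channels: tuple[int, int, int, int],
                 decoder_width: int,
                 cmkd_params: list[CMKDParams] | None = None,
                 rsab_params: RSABParams | None = None,
                 use_cmkd: bool = True, use_rsab: bool = True):
        super().__init__()
        c1, c2, c3, c4 = stage_channels
        self.use_cmkd = use_cmkd
        self.use_rsab = use_rsab
        if use_cmkd:
            if cmkd_params is None:
                cmkd_params = [CMKDParams(c) for c in (c1, c2, c3)]
            self.cmkd = ModuleList(CMKD(p) for p in cmkd_params)
        else:
            self.cmkd = ModuleList(Identity() for _ in range(3))
        if use_rsab:
            self.rsab: Module = ResidualSelfAttention(
                rsab_params if rsab_params is not None else RSABParams(c4))
        else:
            self.rsab = Identity()
        self.cbr = ModuleList(CBR(c, decoder_width) for c in stage_channels)

    def forward(self, features: BackboneFeatures) -> EnhancedFeatures:
        f1, f2, f3, f4 = features.levels()
        fprime = (self.cmkd[0](f1), self.cmkd[1](f2), self.cmkd[2](f3),
                  self.rsab(f4))
        fdp = tuple(cbr(fp) for cbr, fp in zip(self.cbr, fprime))
        return EnhancedFeatures(fprime=fprime, fdp=fdp)
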