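"""Top-down decoder and full model assembly.

The decoder consumes the CBR-projected pyramid f''1..f''4 (common width D).
The top level passes through unchanged (F4 = f''4); levels 3 and 2 are fused
by the attention-based scale interaction module (ASIM), which gates both the
upsampled higher-level decoder feature and the same-resolution encoder
feature with a learned sigmoid weight map; level 1 is fused by the
residual-based scale fusion module (RSFM), a concatenation followed by a
residual block. A x4 bilinear upsampling, a residual block and a 1x1
convolution with sigmoid produce the full-resolution probability map.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .backbone import (BackboneConfig, ConfigurationError, DimensionError,
                       extract_pyramid, make_backbone)
from .encoder import CBR, CMKDParams, EncoderEnhancer, RSABParams, _ReLU
from .layers import BatchNorm2d, Conv2d, Identity, Module, Sequential

__all__ = [
    "ResidualBlock",
    "upsample_block",
    "ASIM",
    "RSFM",
    "MRANet",
    "PROB_EPS",
]

# Numerical guard keeping output probabilities strictly inside (0, 1) even
# when trained logits saturate the sigmoid in float64.
PROB_EPS = 1e-7


class ResidualBlock(Module):
    """Conv-BN-ReLU-Conv-BN main path plus identity / 1x1-BN shortcut."""

    def __init__(self, cin: int, cout: int):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, padding=1)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, padding=1)
        self.bn2 = BatchNorm2d(cout)
        if cin == cout:
            self.shortcut: Module = Identity()
        else:
            self.shortcut = Sequential(Conv2d(cin, cout, 1), BatchNorm2d(cout))

    def forward(self, x: Tensor) -> Tensor:
        main = self.bn2(self.conv2(ad.relu(self.bn1(self.conv1(x)))))
        return ad.relu(main + self.shortcut(x))


def upsample_block(f: Tensor, factor: int) -> Tensor:
    """Bilinear upsampling by a factor of 2 or 4 (align_corners disabled)."""
    if factor not in (2, 4):
        raise ConfigurationError(f"upsampling factor must be 2 or 4, got {factor!r}")
    return ad.bilinear_upsample(f, factor)


def _check_double(f_low: Tensor, f_high: Tensor, where: str) -> None:
    lh, lw = f_low.shape[2:]
    hh, hw = f_high.shape[2:]
    if (lh, lw) != (2 * hh, 2 * hw):
        raise DimensionError(
            f"{where}: low-level feature {f_low.shape} must be exactly double "
            f"the high-level feature {f_high.shape} spatially")


class ASIM(Module):
    """Attention-based scale interaction: gated fusion of adjacent levels.

    The joint feature is the concatenation of the x2-upsampled higher-level
    decoder feature with the same-resolution encoder feature. A CBR, a 3x3
    convolution to one channel, a 3x3 stride-1 average pooling and a sigmoid
    produce the spatial weight map w; w gates 3x3 convolutions of both
    inputs, and the gated features are fused with the joint feature by a
    final CBR back to width D. ``gate_pool='global'`` collapses the weight
    map to one scalar per image instead (alternative reading, off by
    default).
    """

    def __init__(self, width: int, gate_pool: str = "spatial"):
        super().__init__()
        if gate_pool not in ("spatial", "global"):
            raise ConfigurationError(
                f"gate_pool must be 'spatial' or 'global', got {gate_pool!r}")
        d = width
        self.gate_pool = gate_pool
        self.joint_cbr = CBR(2 * d, d)
        self.gate_conv = Conv2d(d, 1, 3, padding=1)
        self.low_conv = Conv2d(d, d, 3, padding=1)
        self.high_conv = Conv2d(d, d, 3, padding=1)
        self.fuse_cbr = CBR(4 * d, d)

    def gate(self, fijo: Tensor) -> Tensor:
        pre = self.gate_conv(self.joint_cbr(fijo))
        if self.gate_pool == "spatial":
            pooled = ad.avgpool2d_3x3(pre)
        else:
            pooled = pre.mean(axis=(2, 3), keepdims=True)
        return ad.sigmoid(pooled)

    def forward(self, f_low: Tensor, f_high: Tensor) -> Tensor:
        _check_double(f_low, f_high, "ASIM")
        up = upsample_block(f_high, 2)
        fijo = ad.concat([up, f_low], axis=1)
        w = self.gate(fijo)
        fil = w * self.low_conv(f_low)
        fih = w * self.high_conv(up)
        return self.fuse_cbr(ad.concat([fil, fih, fijo], axis=1))


class RSFM(Module):
    """Residual-based scale fusion: upsample, concatenate, residual block."""

    def __init__(self, width: int):
        super().__init__()
        self.rb = ResidualBlock(2 * width, width)

    def forward(self, f1dp: Tensor, f2: Tensor) -> Tensor:
        _check_double(f1dp, f2, "RSFM")
        f2up = upsample_block(f2, 2)
        f1con = ad.concat([f2up, f1dp], axis=1)
        return self.rb(f1con)


class _ConcatCBRFusion(Module):
    """Minimal fusion stand-in used when ASIM or RSFM is ablated."""

    def __init__(self, width: int):
        super().__init__()
        self.cbr = CBR(2 * width, width)

    def forward(self, f_low: Tensor, f_high: Tensor) -> Tensor:
        _check_double(f_low, f_high, "fusion")
        return self.cbr(ad.concat([upsample_block(f_high, 2), f_low], axis=1))


class MRANet(Module):
    """Full encoder-decoder segmentation network.

    Parameters
    ----------
    backbone_config : pyramid backbone selection and widths.
    decoder_width : common channel width D of the decoder stream.
    cmkd_params, rsab_params : optional overrides for the encoder blocks.
    use_cmkd, use_rsab, use_asim, use_rsfm : ablation switches; a disabled
        block is replaced by the minimal stand-in (identity for the encoder
        blocks, concat+CBR for the fusion blocks).
    gate_pool : ASIM weight-map pooling mode ('spatial' or 'global').
    """

    def __init__(self, backbone_config: BackboneConfig | None = None,
                 decoder_width: int = 128,
                 cmkd_params: list[CMKDParams] | None = None,
                 rsab_params: RSABParams | None = None,
                 use_cmkd: bool = True, use_rsab: bool = True,
                 use_asim: bool = True, use_rsfm: bool = True,
                 gate_pool: str = "spatial"):
        super().__init__()
        if backbone_config is None:
            backbone_config = BackboneConfig()
        self.backbone_config = backbone_config
        self.decoder_width = decoder_width
        self.use_cmkd = use_cmkd
        self.use_rsab = use_rsab
        self.use_asim = use_asim
        self.use_rsfm = use_rsfm
        d = decoder_width
        self.backbone = make_backbone(backbone_config)
        self.enhancer = EncoderEnhancer(
            backbone_config.stage_channels, d,
            cmkd_params=cmkd_params, rsab_params=rsab_params,
            use_cmkd=use_cmkd, use_rsab=use_rsab)
        if use_asim:
            self.asim3: Module = ASIM(d, gate_pool)
            self.asim2: Module = ASIM(d, gate_pool)
        else:
            self.asim3 = _ConcatCBRFusion(d)
            self.asim2 = _ConcatCBRFusion(d)
        if use_rsfm:
            self.rsfm: Module = RSFM(d)
        else:
            self.rsfm = _ConcatCBRFusion(d)
        self.head_rb = ResidualBlock(d, d)
        self.head_conv = Conv2d(d, 1, 1)

    def forward(self, images) -> Tensor:
        """Forward pass: N x 3 x H x W normalised images -> N x 1 x H x W
        probability map with values strictly in (0, 1)."""
        feats = extract_pyramid(self.backbone, images)
        enhanced = self.enhancer(feats)
        f1dp, f2dp, f3dp, f4dp = enhanced.fdp
        f4 = f4dp
        f3 = self.asim3(f3dp, f4)
        f2 = self.asim2(f2dp, f3)
        f1 = self.rsfm(f1dp, f2)
        up = upsample_block(f1, 4)
        logits = self.head_conv(self.head_rb(up))
        return ad.clip(ad.sigmoid(logits), PROB_EPS, 1.0 - PROB_EPS)

    def predict(self, images) -> np.ndarray:
        """Evaluation-mode probabilities as a plain array."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward(images).data
        finally:
            self.train(was_training)
        return out
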