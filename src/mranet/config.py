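"""Configuration schema, YAML parsing and model construction.

A configuration file has three optional top-level sections - ``model``,
``train`` and ``synth`` - each fully defaulted, so an empty file resolves to
the stock configuration (352x352 transformer backbone, decoder width 128,
Adam at lr 1e-4, batch 16, up to 150 epochs). Unknown keys are rejected with
the offending path; the resolved configuration round-trips through
``resolved_dict`` / ``parse_config`` unchanged and is embedded in every
checkpoint.

Ablation switches (cmkd / rsab / asim / rsfm) select the model variants of
the component study: a disabled encoder block becomes the identity, a
disabled fusion block becomes concat+CBR.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field, fields

import yaml

from .backbone import BackboneConfig, ConfigurationError
from .data import SynthConfig
from .decoder import MRANet
from .encoder import CMKDParams, RSABParams

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "parse_config",
    "build_model",
    "resolved_dict",
]


@dataclass
class AblationFlags:
    cmkd: bool = True
    rsab: bool = True
    asim: bool = True
    rsfm: bool = True


@dataclass
class ModelConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    decoder_width: int = 128
    # CMKD branch width b = round(frac * C). The fraction (with decoder
    # width 128) is calibrated so the full default model totals the published
    # 52.38 M trainable parameters; see docs/methods.md.
    cmkd_branch_frac: float = 0.66
    cmkd_attention_reduction: int = 16
    cmkd_spatial_kernel: int = 7
    cmkd_kernel_sizes: tuple[int, ...] = (1, 3, 7, 11)
    cmkd_dilation_rates: tuple[int, ...] = (1, 3, 7, 11)
    rsab_qk_reduction: int = 8
    ablation: AblationFlags = field(default_factory=AblationFlags)
    gate_pool: str = "spatial"
    eval_threshold: float = 0.5

    def __post_init__(self):
        if self.decoder_width < 1:
            raise ConfigurationError("decoder_width must be >= 1")
        if not 0.0 < self.eval_threshold < 1.0:
            raise ConfigurationError(
                f"eval_threshold must be in (0, 1), got {self.eval_threshold}")
        if self.cmkd_branch_frac <= 0:
            raise ConfigurationError("cmkd_branch_frac must be positive")


@dataclass
class TrainConfig:
    lr: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 150
    optimiser: str = "adam"
    seed: int = 42
    checkpoint_dir: str | None = None
    select_best_by: str = "mDSC"
    augment: bool = True
    max_steps: int | None = None  # optional cap on total optimisation steps

    def __post_init__(self):
        if self.lr <= 0:
            raise ConfigurationError("lr must be positive")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ConfigurationError("batch_size and max_epochs must be >= 1")
        if self.optimiser != "adam":
            raise ConfigurationError(
                f"unsupported optimiser {self.optimiser!r} (only 'adam')")


_TUPLE_FIELDS = {"stage_channels", "stage_strides", "input_size", "size",
                 "polyps_per_image", "blob_radius_frac", "cmkd_kernel_sizes",
                 "cmkd_dilation_rates", "depths", "num_heads", "mlp_ratios",
                 "sr_ratios"}


def _build_section(cls, raw: dict, path: str):
    allowed = {f.name for f in fields(cls)}
    kwargs = {}
    for key, value in raw.items():
        if key not in allowed:
            raise ConfigurationError(
                f"unknown configuration key {path}.{key!r}; "
                f"allowed keys: {sorted(allowed)}")
        if key in _TUPLE_FIELDS and isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"invalid types under {path}: {exc}") from exc


def parse_config(source: str) -> tuple[ModelConfig, TrainConfig, SynthConfig]:
    """Parse a YAML file path or YAML text into fully-resolved configs."""
    if os.path.isfile(source):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(source)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration root must be a mapping")
    unknown = set(raw) - {"model", "train", "synth"}
    if unknown:
        raise ConfigurationError(
            f"unknown top-level configuration keys: {sorted(unknown)}")
    model_raw = dict(raw.get("model") or {})
    backbone_raw = model_raw.pop("backbone", {}) or {}
    ablation_raw = model_raw.pop("ablation", {}) or {}
    backbone = _build_section(BackboneConfig, backbone_raw, "model.backbone")
    ablation = _build_section(AblationFlags, ablation_raw, "model.ablation")
    model_raw["backbone"] = backbone
    model_raw["ablation"] = ablation
    model = _build_section(ModelConfig, model_raw, "model")
    train = _build_section(TrainConfig, dict(raw.get("train") or {}), "train")
    synth = _build_section(SynthConfig, dict(raw.get("synth") or {}), "synth")
    return model, train, synth


def resolved_dict(model: ModelConfig, train: TrainConfig | None = None,
                  synth: SynthConfig | None = None) -> dict:
    """The fully-resolved configuration as a plain mapping (YAML-safe)."""
    model_d = asdict(model)
    backbone_d = model_d.pop("backbone")
    ablation_d = model_d.pop("ablation")
    model_d = {"backbone": _listify(backbone_d), "ablation": ablation_d,
               **_listify(model_d)}
    out = {"model": model_d}
    if train is not None:
        out["train"] = asdict(train)
    if synth is not None:
        out["synth"] = _listify(asdict(synth))
    return out


def _listify(d: dict) -> dict:
    return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}


def build_model(config: ModelConfig) -> MRANet:
    """Construct the network described by a resolved model configuration."""
    chans = config.backbone.stage_channels
    cmkd_params = None
    if config.ablation.cmkd:
        cmkd_params = [
            CMKDParams(
                in_channels=c,
                branch_width=max(1, round(config.cmkd_branch_frac * c)),
                kernel_sizes=config.cmkd_kernel_sizes,
                dilation_rates=config.cmkd_dilation_rates,
                attention_reduction=config.cmkd_attention_reduction,
                spatial_kernel=config.cmkd_spatial_kernel,
            )
            for c in chans[:3]
        ]
    rsab_params = None
    if config.ablation.rsab:
        rsab_params = RSABParams(channels=chans[3],
                                 qk_reduction=config.rsab_qk_reduction)
    return MRANet(
        backbone_config=config.backbone,
        decoder_width=config.decoder_width,
        cmkd_params=cmkd_params,
        rsab_params=rsab_params,
        use_cmkd=config.ablation.cmkd,
        use_rsab=config.ablation.rsab,
        use_asim=config.ablation.asim,
        use_rsfm=config.ablation.rsfm,
        gate_pool=config.gate_pool,
    )
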