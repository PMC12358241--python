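import numpy as np
import pytest

from mranet import BackboneConfig, ModelConfig, SynthConfig, build_model
from mranet.layers import set_seed


def tiny_model_config(input_size=(96, 96), **overrides) -> ModelConfig:
    """Desk-scale model: tiny convolutional backbone, narrow decoder."""
    kwargs = dict(
        backbone=BackboneConfig(variant="tiny_conv",
                                stage_channels=(8, 16, 32, 64),
                                input_size=input_size),
        decoder_width=32,
        cmkd_branch_frac=0.5,
        cmkd_attention_reduction=2,
        rsab_qk_reduction=4,
    )
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


@pytest.fixture()
def tiny_model():
    set_seed(42)
    return build_model(tiny_model_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def synth_config():
    return SynthConfig(n_images=4, size=(64, 64), seed=7)
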