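"""Training, evaluation, checkpointing and visualisation.

The training recipe follows the published setup: Adam at learning rate 1e-4,
batch size 16, up to 150 epochs, hybrid BCE+Dice loss on the final
probability map only, with random rotation / horizontal flip / vertical flip
augmentation on the training split. Model selection keeps the checkpoint
with the best validation mDSC. Every source of randomness (initialisation,
data order, augmentation) is seeded, so identical seeds reproduce identical
loss curves.

Checkpoints are numpy ``.npz`` archives holding every parameter and buffer
plus the fully-resolved configuration as JSON, so loading rebuilds a model
producing bitwise-identical predictions.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from . import config as cfg
from .data import SegSample, augment, batch_tensors
from .decoder import MRANet
from .layers import Adam, Module
from .losses import hybrid_loss
from .metrics import MetricsReport, evaluate_dataset

__all__ = [
    "TrainHistory",
    "train",
    "evaluate",
    "count_parameters",
    "parameters_in_millions",
    "freeze",
    "save_checkpoint",
    "load_checkpoint",
    "predict_heatmap",
]


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_metric: float = -np.inf
    best_checkpoint: str | None = None

    @property
    def loss_curve(self) -> list[float]:
        return [e["total"] for e in self.epochs]


def count_parameters(model: Module, trainable_only: bool = True) -> int:
    """Total number of parameter elements."""
    return sum(p.size for p in model.parameters()
               if p.requires_grad or not trainable_only)


def parameters_in_millions(model: Module, trainable_only: bool = True) -> float:
    """Parameter count in millions, rounded to two decimals."""
    return round(count_parameters(model, trainable_only) / 1e6, 2)


def freeze(module: Module) -> None:
    """Mark every parameter of a module as non-trainable."""
    for p in module.parameters():
        p.requires_grad = False


def _forward_batch(model: MRANet, samples: list[SegSample],
                   size: tuple[int, int]):
    images, masks = batch_tensors(samples, size)
    return model(images), masks


def train(model: MRANet, train_samples: list[SegSample],
          val_samples: list[SegSample], config: cfg.TrainConfig,
          model_config: cfg.ModelConfig | None = None,
          val_every: int = 1) -> TrainHistory:
    """Optimise the model on the training split; select by validation mDSC.

    Augmentation is applied to training samples only. Training stops after
    ``config.max_epochs`` epochs or ``config.max_steps`` optimisation steps,
    whichever comes first. A non-finite loss aborts with a diagnostic naming
    the epoch and step.
    """
    if not train_samples or not val_samples:
        raise ValueError("training and validation sets must be non-empty")
    size = model.backbone_config.input_size
    rng = np.random.default_rng(config.seed)
    optimiser = Adam(model.parameters(), lr=config.lr)
    history = TrainHistory()
    step = 0
    for epoch in range(config.max_epochs):
        model.train()
        order = rng.permutation(len(train_samples))
        epoch_losses = {"bce": [], "dice": [], "total": []}
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = [train_samples[i] for i in idx]
            if config.augment:
                batch = [augment(s, int(rng.integers(0, 2**31))) for s in batch]
            pred, masks = _forward_batch(model, batch, size)
            losses = hybrid_loss(pred, masks)
            total = losses.total.item()
            if not np.isfinite(total):
                raise RuntimeError(
                    f"non-finite loss {total} at epoch {epoch}, step {step}")
            optimiser.zero_grad()
            losses.total.backward()
            optimiser.step()
            for key, value in losses.as_floats().items():
                epoch_losses[key].append(value)
            step += 1
            if config.max_steps is not None and step >= config.max_steps:
                break
        record = {"epoch": epoch, "steps": step}
        record.update({k: float(np.mean(v)) for k, v in epoch_losses.items()})
        do_val = (epoch % val_every == 0
                  or epoch == config.max_epochs - 1
                  or (config.max_steps is not None and step >= config.max_steps))
        if do_val:
            report = evaluate(model, val_samples)
            record["val"] = report.means
            metric = report.means[config.select_best_by]
            if metric > history.best_metric:
                history.best_metric = metric
                history.best_epoch = epoch
                if config.checkpoint_dir is not None:
                    os.makedirs(config.checkpoint_dir, exist_ok=True)
                    path = os.path.join(config.checkpoint_dir, "best.npz")
                    save_checkpoint(model, path, model_config)
                    history.best_checkpoint = path
        history.epochs.append(record)
        if config.max_steps is not None and step >= config.max_steps:
            break
    return history


def evaluate(model: MRANet, samples: list[SegSample],
             threshold: float = 0.5, batch_size: int = 8) -> MetricsReport:
    """Forward, binarise and score a sample list at network resolution."""
    if not samples:
        raise ValueError("evaluate requires at least one sample")
    size = model.backbone_config.input_size
    preds, gts = [], []
    for start in range(0, len(samples), batch_size):
        chunk = samples[start:start + batch_size]
        images, masks = batch_tensors(chunk, size)
        probs = model.predict(images)
        preds.extend(probs[i, 0] for i in range(len(chunk)))
        gts.extend(masks[i, 0] for i in range(len(chunk)))
    return evaluate_dataset(preds, gts, threshold=threshold)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: MRANet, path: str,
                    model_config: cfg.ModelConfig | None = None) -> None:
    state = model.state_dict()
    meta = {}
    if model_config is not None:
        meta["config"] = cfg.resolved_dict(model_config)
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str,
                    model: MRANet | None = None) -> tuple[MRANet, dict]:
    """Rebuild (or refill) a model from a checkpoint.

    Without ``model``, the embedded configuration is required and is used to
    reconstruct the architecture before loading weights.
    """
    with np.load(path) as archive:
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
        meta = json.loads(archive["__meta__"].tobytes().decode()) \
            if "__meta__" in archive.files else {}
    if model is None:
        if "config" not in meta:
            raise ValueError(
                "checkpoint has no embedded configuration; pass a model")
        import yaml
        model_cfg, _, _ = cfg.parse_config(yaml.safe_dump(
            {"model": meta["config"]["model"]}))
        model = cfg.build_model(model_cfg)
    model.load_state_dict(state)
    return model, meta


# ---------------------------------------------------------------------------
# visualisation
# ---------------------------------------------------------------------------

def predict_heatmap(model: MRANet, sample: SegSample, out_dir: str,
                    alpha: float = 0.5) -> dict[str, str]:
    """Write the probability map (grayscale) and a colour overlay.

    Both outputs are at the sample's native resolution. The colour map is
    monotone (matplotlib 'jet'): probability 0 maps to the coldest colour,
    1 to the hottest.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"overlay alpha must be in [0, 1], got {alpha}")
    from matplotlib import colormaps
    os.makedirs(out_dir, exist_ok=True)
    size = model.backbone_config.input_size
    images, _ = batch_tensors([sample], size)
    prob = model.predict(images)[0, 0]
    h, w = sample.image.shape[:2]
    prob_native = np.asarray(
        Image.fromarray(prob.astype(np.float32), mode="F").resize(
            (w, h), Image.BILINEAR))
    prob_native = np.clip(prob_native, 0.0, 1.0)
    gray_path = os.path.join(out_dir, f"{sample.id}_prob.png")
    Image.fromarray((prob_native * 255).astype(np.uint8)).save(gray_path)
    cmap = colormaps["jet"]
    heat = (cmap(prob_native)[..., :3] * 255).astype(np.float64)
    overlay = ((1 - alpha) * sample.image.astype(np.float64)
               + alpha * heat)
    overlay_path = os.path.join(out_dir, f"{sample.id}_overlay.png")
    Image.fromarray(np.clip(overlay, 0, 255).astype(np.uint8)).save(overlay_path)
    return {"probability": gray_path, "overlay": overlay_path}
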