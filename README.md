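# mranet

A multi-dimensional residual attention network for binary polyp
segmentation in endoscopy images, implemented as a reusable library and
CLI, together with its training recipe, a boundary-aware evaluation suite
and a synthetic-fixture generator so everything runs end-to-end on one CPU
without downloads.

Automated polyp segmentation supports early colorectal-cancer screening:
the network takes an RGB endoscopy frame and produces a per-pixel
probability that each pixel belongs to a polyp. The architecture is an
encoder–decoder:

* a **PVTv2-B2** transformer backbone yields a feature pyramid f1..f4 at
  strides 4/8/16/32 (a `tiny_conv` variant honours the same contract for
  desk-scale tests);
* **CMKD** blocks (parallel 1/3/7/11 kernels, then parallel 3×3 dilated
  convolutions at rates 1/3/7/11, residual shortcut, channel+spatial
  attention) refine f1..f3, and a residual self-attention block (**RSAB**)
  refines f4: f′₄ = f₄ + Conv(Reshape(V · softmax(QᵀK)));
* the decoder fuses top-down: F4 = f″4, F3/F2 via the gated
  attention-based scale interaction module (**ASIM**), F1 via the residual
  scale-fusion module (**RSFM**), then
  Fout = σ(Conv1×1(RB(Up×4(F1))));
* training minimises L = L_BCE + L_Dice (Adam, lr 1e-4, batch 16, up to
  150 epochs, flip/rotation augmentation);
* evaluation reports per-image mIoU, mDSC, Recall, Precision, F2 (β = 2)
  and the exact boundary Hausdorff distance, with dataset means.

The full default configuration counts **52.48 M** trainable parameters
(the published budget for this architecture is 52.38 M). There is no
deep-learning framework dependency: the network runs on a small
reverse-mode autodiff engine over numpy that ships inside the package and
is verified against finite differences. See `docs/methods.md` for the
model, the calibration of the open widths, and the design decisions.

## Worked example

Generate a synthetic dataset, overfit the desk-scale model (tiny backbone,
96×96 inputs, 200 steps ≈ 5 min on one CPU core) and evaluate it:

```bash
mranet synth --config configs/desk.yaml --out /tmp/polyps
mranet train --config configs/desk.yaml --synthetic --checkpoint-dir /tmp/ckpt
mranet eval  --checkpoint /tmp/ckpt/best.npz --data /tmp/polyps --report /tmp/report.csv
mranet params --config configs/desk.yaml
```

The CLI holds out 2 of the 8 synthetic images for validation and prints
one line per epoch (6 images at batch 8 means one optimisation step per
epoch):

```
epoch   0 loss 1.5285 (bce 0.7485 dice 0.7800) val mDSC 0.3924
epoch   1 loss 0.8699 (bce 0.3568 dice 0.5131) val mDSC 0.3789
...
epoch 198 loss 0.0093 (bce 0.0021 dice 0.0071) val mDSC 0.7580
epoch 199 loss 0.0090 (bce 0.0021 dice 0.0069) val mDSC 0.7558
best epoch 12: /tmp/ckpt/best.npz
```

The training loss falls from ≈1.5 to ≈0.01 (the model memorises its six
training blobs), while the two held-out images plateau around mDSC 0.75 —
with six training images there is nothing to generalise from, and the best
validation checkpoint is selected early (epoch 12 here). Evaluating that
checkpoint on the full 8-image folder prints the dataset means:

```
mIoU: 0.8017
mDSC: 0.8868
Recall: 0.8704
Precision: 0.9109
F2: 0.8761
HD: 16.3295
```

mDSC 0.89 means the predicted masks overlap the references well on
average; the Hausdorff mean of ≈16 px (at the 96×96 evaluation
resolution) reflects the two imperfectly-fitted held-out images.
`mranet params --config configs/desk.yaml` prints
`trainable parameters: 443896 (0.44 M)` for this reduced configuration;
with no `--config` (full defaults) it prints
`trainable parameters: 52484724 (52.48 M)`.

The five component-study configurations (each of CMKD/RSAB/ASIM/RSFM
disabled in turn, plus the full model) ship as `configs/*.yaml`.

Python API equivalent:

```python
from mranet import SynthConfig, generate_synthetic, build_model, parse_config
from mranet.config import TrainConfig
from mranet.engine import train, evaluate
from mranet.layers import set_seed

model_cfg, train_cfg, synth_cfg = parse_config("configs/desk.yaml")
samples = generate_synthetic(synth_cfg)
set_seed(train_cfg.seed)
model = build_model(model_cfg)
history = train(model, samples, samples, train_cfg, val_every=50)
print(evaluate(model, samples).means)
```

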