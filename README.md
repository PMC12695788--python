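# berrydetr

Detection and counting of small, densely clustered fruit (bayberries and
similar near-circular targets) in complex orchard imagery, built as an
end-to-end query-based detector — no anchor tuning, no non-maximum
suppression — together with the dataset tooling and metrics needed to train
and evaluate it.

The package is aimed at researchers in agricultural image analysis who want
a lightweight real-time detection-transformer variant specialised for small
targets, and at anyone studying the three architectural ideas it implements:

* **EFENet backbone** — four stages of multi-path feature-enhancement
  modules (MFEM). Each MFEM expands its input with a 1×1 convolution,
  splits it into a preserved branch F₁ and a processed branch F₂, runs F₂
  through a **reparameterized convolution** (RepConv) and a cascade of n−1
  further 3×3 convolutions, and fuses everything with a closing 1×1:

      Y = W_cv2 ∗ Concat[F₁, F_rep, F_m1, …, F_m(n−1), F_cv4]

  RepConv trains with three parallel branches (3×3, 1×1, identity-via-BN)
  and collapses at inference into a single 3×3 kernel with *identical*
  output: W_equiv = W₃ₓ₃^fused + Pad₃ₓ₃(W₁ₓ₁^fused) + W_id^fused.

* **MDFFN neck** — a P2–P5 fusion pyramid in which downsampling is a
  lossless space-to-depth rearrangement followed by a 3×3 convolution
  (SPDConv), each fusion node is a cross-stage multi-kernel block
  (CMKBlock: a thin 25%-channel branch through depthwise 1×1 / 1×31 / 31×1
  / 31×31 kernels), and features are modulated in *both* domains: a
  dual-domain attention module gates the 2-D FFT of the map channel-wise
  (F_fca = |F⁻¹(W_fca·GAP(x) ⊙ F(x))|) and a frequency-modulation block
  mixes a spatial gate with a sibling branch's spectrum
  (α ⊙ |F⁻¹(W₁x ⊙ F(W₂x))| + β ⊙ x).

* **ADSample** — learnable deformable downsampling. Each output location
  samples N continuous input positions P = P₀ + Pₙ + Δ (regular grid +
  pattern template + offsets predicted by a stride-matched 3×3
  convolution), reads them by bilinear interpolation, and aggregates with
  an (N,1) column convolution + SiLU. With zero offsets it reduces exactly
  to a patterned strided convolution.

Everything runs on a small numpy reverse-mode autodiff core
(`berrydetr.nn`) — convolutions, FFT attention, deformable sampling,
Hungarian-matched detection losses and AdamW are all implemented on
numpy/scipy, so the package trains and evaluates small models on a plain
CPU with no deep-learning framework installed.

## Worked example

Assemble the default full model and the baseline and print their complexity
(the numbers are computed live — parameters by exact summation, GFLOPs by a
counted 640×640 forward pass, two FLOPs per multiply-accumulate):

```text
$ berrydetr build --variant mde_detr
variant:     mde_detr
parameters:  14,718,852  (14.7 M)
  backbone  5.277 M
  encoder   5.790 M
  decoder   3.652 M
  P2/4: 64ch 160x160, 3 MFEM (n=2), 0.100 M
  P3/8: 128ch 80x80, 3 MFEM (n=2), 0.481 M
  P4/16: 256ch 40x40, 3 MFEM (n=1), 1.354 M
  P5/32: 512ch 20x20, 1 MFEM (n=2), 3.323 M
complexity:  27.8 GMACs = 55.6 GFLOPs @ 640

$ berrydetr build --variant rtdetr_r18 --no-flops
variant:     rtdetr_r18
parameters:  19,796,394  (19.8 M)
  backbone  11.177 M
  encoder   4.968 M
  decoder   3.652 M
```

The full model is a quarter smaller than the baseline it replaces (25.76%
on the one-decimal counts) while keeping the decoder untouched. Train a reduced model (2 decoder layers, 64-wide
fusion, 128×128 input) on 20 synthetic orchard scenes and score it on its
own training set:

```python
import numpy as np
from berrydetr import nn
from berrydetr.data_pipeline import SceneParams, generate_dataset
from berrydetr.detector import ModelConfig, assemble, infer
from berrydetr.efenet import EFENetConfig
from berrydetr.evaluation import CountRecord, count_regression
from berrydetr.train import evaluate_detector, train_detector

nn.set_seed(0)
scene = SceneParams(size=128, berries_mean=3, radius_range=(10, 18),
                    occlusion_fraction=0.1, clutter=6, red_fraction=1.0,
                    illumination_range=(0.85, 1.15))
items = generate_dataset(20, scene, seed=1)
cfg = ModelConfig(num_classes=1, input_size=128,
                  efenet=EFENetConfig((16, 32, 64, 128), (1, 1, 1, 1), (1, 1, 1, 1), 8),
                  fusion_width=64, spd_reduce=32, p2_reduce=16, strip_length=9,
                  decoder_layers=2, num_queries=30, hidden=64, heads=4, points=4,
                  ffn=128, adsample_n=4)
model = assemble("mde_detr", cfg=cfg)
losses = train_detector(model, items, steps=200, lr=2e-3, batch_size=4, seed=0)
map50, map5095 = evaluate_detector(model, items)
recs = [CountRecord(it.image_id, len(infer(model, [it.image], 0.5)[0]),
                    float(len(it.boxes))) for it in items]
r = count_regression(recs)
```

Output of this exact script (about two minutes on one CPU core):

```text
loss: 16.77 -> 2.22
training-set mAP50 = 100.0%, mAP50:95 = 71.9%
counting: slope=0.889 intercept=0.198 R2=0.9698 MAE=0.20 RMSE=0.45
```

The model memorises the 20 scenes (mAP50 100% at IoU 0.5; the stricter
50:95 average is lower because box edges are only pixel-accurate), and the
detection-to-counting regression of machine counts on ground-truth counts is
tight (R² ≈ 0.97, mean absolute miscount 0.2 berries per image).

The CLI also covers the dataset pipeline and evaluation:
`berrydetr synth | split | augment | train | infer | eval | count | fuse`
(`fuse` converts a trained multi-branch checkpoint into its single-branch
inference form; weights are stored as `.npz` archives of the
`state_dict()` arrays, keyed by dotted module paths such as
`backbone.stages.0.0.rep.conv3.weight`).

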