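# fecnet

Fine-grained four-class stool image classification (diarrhea / lack of water /
normal / soft stool), implemented in pure NumPy:

- **`fecnet.nn`** — a small reverse-mode autograd engine with the layers the
  project needs (grouped/depthwise/pointwise convolution, batch norm, max
  pooling, linear, Adam, cross-entropy). No deep-learning framework required.
- **`fecnet.conv_primitives`** — depthwise separable convolution (DSC) with
  closed-form parameter/FLOP accounting (`K²CN` vs `K²C + CN`, ratio
  `1/N + 1/K²`), and the squeeze-and-excitation channel gate.
- **`fecnet.clam`** — coordinate location attention: directional average
  pooling along height and width, a location-attention unit (smoothing pool →
  per-position fully-connected path ⊙ 3×3 DSC path), a third branch carrying
  the global channel descriptor, fused by channel softmax and applied
  multiplicatively.
- **`fecnet.madm`** — multi-scale attention down-sampling: parallel stride-2
  max-pool / 5×5 DSC / 7×7 DSC branches, concatenated, projected 1×1 and gated
  by squeeze-excitation; exact trainable-weight accounting included.
- **`fecnet.backbone`** — split-attention bottleneck blocks (radix/cardinal
  soft weighting with R-softmax: softmax over radix when r > 1, sigmoid when
  r = 1), the 14-scheme ablation grid (block type × attention × conv type ×
  down-sampling), presets `resnet_ref` / `scmnet` / `mc_scmnet`, and parameter
  counting. The `resnet_ref` baseline with a 1000-class head counts exactly
  25.557 M trainable parameters.
- **`fecnet.data`** — image-folder ingestion, the augmentation protocol (50 %
  Gaussian blur σ ∈ [0, 0.5], contrast jitter, per-pixel/per-channel Gaussian
  noise, 20 % brightness shifts, affine warps; exactly one variant per
  original), five-fold splitting, and a seed-deterministic synthetic generator
  that renders the four stool morphologies over cluttered backgrounds with
  leaf/stone/twig distractors.
- **`fecnet.evaluation`** — confusion-matrix metrics (per-class and three
  aggregate modes), one-way ANOVA with the F test, and Grad-CAM heatmaps.
- **`fecnet.cli` / `fecnet.harness`** — experiment orchestration with the
  reference protocol defaults (Adam, lr 1e-4, batch 8, 130 epochs, 224×224,
  5 folds).

## CLI

```bash
# generate a synthetic dataset
fecnet synth --out data/synth --n-per-class 50 --image-size 64 --seed 0

# train a reduced-width model quickly on it
fecnet train --model mc_scmnet --data data/synth --epochs 3 --seed 1 \
    --image-size 64 --base-width 8 --stem-channels 8 --depths 1,1,1,1 --out run

# cross-validation, parameter report, prediction, heatmaps, metrics
fecnet crossval --model scmnet --data data/synth --folds 5 --epochs 1 \
    --image-size 64 --base-width 8 --stem-channels 8 --depths 1,1,1,1
fecnet params --scheme 1            # 25.557 M with the 1000-class head
fecnet predict --checkpoint run/checkpoint.npz --config run/config.yaml img.png
fecnet gradcam --checkpoint run/checkpoint.npz --config run/config.yaml img.png
fecnet eval --predictions preds.csv
```

`--model` accepts `resnet_ref`, `scmnet`, `mc_scmnet` or `scheme1`…`scheme14`
(the ablation grid). Full-width training at 224×224 is supported but slow in
NumPy; the reduced-width options above are the intended desk-scale setting.

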