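# posam-ultra

Segmentation of lower-grade glioma (LGG) abnormality on brain MRI slices with
an attention-gated, four-channel encoder–decoder network, tuned by a
polar-bear foraging metaheuristic and evaluated with a full overlap- and
surface-distance metric suite.  The package is aimed at researchers who want
a self-contained, CPU-sized, fully deterministic reimplementation of this
family of pipelines — every component, including a synthetic glioma-phantom
generator, is exercised by the test suite at desk scale.

## The method

**Inputs.** Each slice enters the network as four channels
`X ∈ ℝ^{4×H×W}`: three MRI-like intensity channels plus a *prior channel* —
a tumor-likelihood map computed without learned weights: brain-region
estimate (automatic threshold, largest connected component, holes filled),
within-brain z-scoring, K-means intensity clustering (k = 3), selection of
the highest-mean cluster, 3×3 morphological closing + median filtering, a
distance-to-boundary softening, and min–max scaling to [0, 1].  Because of
the z-score stage the prior is invariant to affine intensity changes
`aI + b` (a > 0).

**Network.** A 7×7 stride-2 stem (+ batch norm, ReLU, 2×2 max-pool) feeds a
hierarchy of DownBlocks (two 3×3 conv+BN+ReLU blocks, the first stride-2
when downsampling), each refined by CBAM — sequential channel attention
`M_c = σ(MLP(avgpool F) + MLP(maxpool F))` and spatial attention
`M_s = σ(f^{7×7}[avgpool; maxpool])`.  The decoder uses *extended* skip
connections: at each stage the upsampled deep feature is concatenated with
the attention-gated matching encoder feature
(`α = σ(ψ(ReLU(W_s·skip + W_g·up(gate))))`) and with all shallower encoder
features (average-pooled and 1×1-reduced), then fused by a 3×3 conv and a
CBAM.  A 1×1 conv + sigmoid yields the segmentation probability `S`;
auxiliary sigmoid heads at 1/4 and 1/2 resolution provide deep supervision

    L_total = L_main + λ₁ L_aux1 + λ₂ L_aux2,

with each `L` a weighted composite of binary cross-entropy, soft Dice and
focal losses.  The network runs on a small reverse-mode autodiff engine
built into the package (`posam_ultra.autograd`), so everything is plain
numpy and exactly reproducible on CPU.

**Hyperparameter tuning (PBFO).** A population of `m` candidate vectors over
a mixed search space (log-scaled learning rate and weight decay, discrete
batch sizes and filter counts, categorical optimizer, continuous dropout,
momentum and loss weights) alternates an exploration update

    H_i ← H_i + α·R₁⊙(H_best − H_i) + β·R₂⊙(H_j − H_k)

with an exploitation contraction `H_i ← H_i + γ·(H_best − H_i)`; the
exploit probability grows as `t/T_max` and α, β, γ follow linear schedules,
with greedy move acceptance.  Fitness is the validation Dice of a proxy
training run (or an analytic surrogate for benchmarking).

**Metrics.** Dice, IoU, pixel accuracy, precision, recall, specificity, F1,
95th-percentile Hausdorff distance (HD95), average symmetric surface
distance (ASSD), median surface distance (MSD) and SSIM.

## Worked example

```python
import posam_ultra as pu
from posam_ultra.training import prepare_inputs, train, evaluate

spec = pu.PhantomSpec()                       # 64x64, one 5% tumor
train_set = pu.generate_dataset(200, spec, seed=11)
val_set   = pu.generate_dataset(20, spec, seed=12)
test_set  = pu.generate_dataset(50, spec, seed=13)

data = {"train": prepare_inputs(*train_set, seed=0),
        "val":   prepare_inputs(*val_set, seed=1)}
record = train(pu.NetworkConfig.tiny(),       # 8 filters, 3 stages
               pu.TrainConfig(epochs=15, patience=15),
               pu.LossWeights(), data, checkpoint_path="ck.npz")
print(f"best val dice {record.best_val_dice:.3f} at epoch {record.best_epoch}")

x_te, y_te = prepare_inputs(*test_set, seed=2)
_, mean = evaluate("ck.npz", x_te, y_te)
print(f"test dice {mean.dice:.3f}  iou {mean.iou:.3f}  hd95 {mean.hd95:.2f}")
```

Output from this exact run:

```
best val dice 0.962 at epoch 13
test dice 0.962  iou 0.927  hd95 1.01
```

i.e. after ~1 minute of CPU training the tiny model recovers 96% of tumor
pixels (Dice) on held-out phantoms with sub-pixel median boundary error.
The same pipeline is exposed on the command line:

```bash
posam generate-data --out data --n 200 --seed 0
posam train --config cfg.yaml --data data --run-dir run
posam eval --checkpoint run/checkpoint.npz --data data --out metrics.csv
posam tune --surrogate --seed 1          # optimizer benchmark
```

## Layout

| module | contents |
| --- | --- |
| `posam_ultra.phantom` | phantom generator, resize/normalize/augment/split, TIFF/PNG pair I/O |
| `posam_ultra.prior` | prior-channel pipeline and four-channel assembly |
| `posam_ultra.autograd` / `nn` / `optim` | autodiff engine, layers, optimizers |
| `posam_ultra.network` | CBAM, attention gates, extended-skip decoder, deep supervision |
| `posam_ultra.losses` | BCE / Dice / focal, composite and deeply-supervised totals |
| `posam_ultra.pbfo` | polar-bear foraging optimization over the mixed search space |
| `posam_ultra.metrics` | overlap, confusion, surface-distance and SSIM metrics |
| `posam_ultra.training` | training loop, checkpoints, prediction, evaluation |
| `posam_ultra.cli` | `posam` command-line interface |

See `docs/methods.md` for modeling assumptions, parameter choices and known
limitations.
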