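# seedsortnet

Industrial seed sorting asks a narrow question at very high throughput: is
the object in this frame one intact seed of the target type, or something
else (several seeds, a stone, a leaf, a broken or defective seed)?  CNN
classifiers answer it well, but production sorters run on embedded hardware
where multi-million-parameter backbones are impractical.  This package
implements a lightweight CNN designed for that setting — ~0.4M parameters
and ~512M multiply-accumulates at 224×224 input — for anyone studying
compact architectures for agricultural vision: the network itself, an exact
parameter/FLOP profiler, a synthetic two-class seed benchmark, and the
training/evaluation recipe.

The architecture combines four ingredients:

* a **dual-branch stem** (strided convolution ∥ anti-aliased pooling,
  concatenated) that halves resolution while keeping shallow texture cues;
* the **Shield block**, a dual-branch inverted-residual unit: a sandglass
  main path `DW3×3 → PW↓C/t (linear) → PW↑ (ReLU6) → DW3×3 (linear)`
  concatenated with a depthwise-separable sub-branch carrying `1/r` of the
  output channels, plus an identity shortcut when widths match;
* **MaxBlurPool** downsampling — dense 2×2 max, fixed binomial blur, then
  stride-2 subsampling — which restores shift-robustness that plain strided
  max pooling destroys;
* **sub-feature space attention (SFSAM)**: channels split into g groups,
  each gated by a spatial attention map built from its channel-wise max/mean
  descriptors through a per-group 7×7 convolution and a softmax over
  positions, applied residually (`F̂ = M⊗F ⊕ F`).

Everything — forward passes, gradients, SGD — is implemented in NumPy
(channels-last), so the package runs anywhere without a deep-learning
framework.  See `docs/methods.md` for the model details and design
decisions.

## Worked example

Profile the default network and the published variants:

```
$ seedsortnet reconcile
    variant   params  params_M   macs_M      printed P/M         diff P/M
    default   400249    0.4002   511.01       0.4/512.06     0.0002/-1.05
   no_sfsam   398665    0.3987   504.48     0.399/505.26    -0.0003/-0.78
         g1   399061    0.3991   506.11     0.399/506.56     0.0001/-0.45
         g4   400249    0.4002   511.01       0.4/512.06     0.0002/-1.05
         g8   401833    0.4018   517.54     0.402/518.85    -0.0002/-1.31
        g16   405001    0.4050   530.60     0.405/532.45        0.0/-1.85
 width_0.75   244746    0.2447   334.66      0.23/338.64     0.0147/-3.98
```

Each row is one network variant: the learnable-parameter count (raw and in
millions), the multiply-accumulate count at 224×224 input in millions (one
MAC = one FLOP, convolution and classifier arithmetic only), the published
figures, and the differences.  Parameters match the published budgets at
their printed precision for every variant except the 0.75× width multiplier,
whose published parameter count is internally inconsistent with its own FLOP
figure (`docs/methods.md` has the argument); MACs agree within 0.2–1.2%.

Generate a synthetic dataset and train on it:

```
$ seedsortnet generate --n-per-class 100 --noise-sd 0 --seed 0 --out data/
wrote 200 images under data

$ seedsortnet train --data data/ --epochs 15 --batch-size 16 --seed 0 --out run/
epoch 15: train_acc=0.9600 test_acc=1.0000

$ seedsortnet evaluate --data data/ --run run/ --out eval/
{"accuracy": 0.97, "auc": 0.9948}
```

The 200 noiseless 100×100 images are split 150/50; after 15 epochs of the
published recipe (SGD, momentum 0.9, lr 1e-3) the network classifies the
held-out split perfectly and scores 0.97 accuracy / 0.995 AUC over the full
set.  `run/` holds the checkpoint, the per-epoch history CSV and a manifest
with config, seeds and artifact checksums; `eval/` holds the confusion
counts, accuracy/precision/recall/F1, AUC and the ROC points.

The same functionality is available as a library:

```python
from seedsortnet import NetworkConfig, build_network, profile

net = build_network(NetworkConfig(groups=8), seed=0)
print(profile(net).params_m)   # 0.401833
```

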