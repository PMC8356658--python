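# Methods

This package implements a lightweight dual-branch convolutional network for
two-class seed-image sorting, together with a deterministic parameter/MAC
profiler, a synthetic seed-image benchmark, and the training/evaluation
recipe the architecture was designed for.  The network, all backward passes,
and the SGD trainer are written directly in NumPy (channels-last float32);
image I/O goes through Pillow and the command line through click.

## The architecture

The backbone is a stack of three bespoke blocks.

**Root stem.**  A 3×3 convolution with 16 filters reads the RGB input at
full resolution.  Its output feeds two parallel downsampling branches: an
anti-aliased max pool (below), and a 3×3/stride-2 convolution with 52
filters followed by a 1×1 reduction to 16 channels.  Concatenating the
branches gives 32 channels at half resolution.  The published description
leaves both branch widths open; 52 is the smallest-residual width under the
budget reconciliation below, and both widths are configuration fields.

**Shield block** (an inverted-residual variant).  For a block with output
width `C` and reduction rate `t`, the main branch runs

    DW 3×3 (ReLU6) → PW 1×1 → round(C/t) channels (linear)
    → PW 1×1 → C − ceil(C/6) channels (ReLU6) → DW 3×3 (linear)

and a parallel sub-branch applies a depthwise-separable 3×3 carrying the
remaining `ceil(C/6)` channels, a different receptive field than the main
path.  The two branches concatenate exactly back to `C`; blocks whose input
and output widths match add an identity shortcut.  The first block of each
stage widens the features and uses `t = 2` (less bottlenecking on narrow
inputs, and a shortcut is impossible anyway); all others use `t = 6` with a
shortcut.  The linear activations after the reducing pointwise layer and the
final depthwise layer avoid zeroing low-dimensional representations.

**MaxBlurPool.**  All four downsampling stages (and the stem's pooled
branch) use anti-aliased pooling: a dense (stride-1) 2×2 max with edge
replication on the right/bottom border, a fixed 3×3 binomial blur
(`[1,2,1]ᵀ[1,2,1]/16`, reflect padding, so constants pass through exactly),
and stride-2 subsampling from the origin.  Output sides are `ceil(H/2)`.
Strided max pooling aliases — a one-pixel input shift can flip which
elements are sampled — and the low-pass blur before subsampling suppresses
that; the test suite measures the effect directly against plain 2×2/stride-2
max pooling over ≥100 random inputs.

**Sub-feature space attention (SFSAM).**  At four sites the `C` channels are
split into `g` contiguous groups (default `g = 4`).  Each group is reduced
along the channel axis to a two-channel descriptor (per-position max and
mean), convolved with a per-group 7×7 filter (2→1 channels, bias, no batch
norm), and gated.  The gate normalizes the score map with a softmax over the
H×W positions, giving an attention map in [0, 1] that sums to one over
positions; the group is then re-weighted residually, `F̂ = M⊗F ⊕ F`, and
the groups are concatenated back.  Two readings were genuinely open:

* *Softmax axis.*  A one-channel map admits no channel-wise softmax; the
  softmax is taken over spatial positions (the only non-degenerate reading).
  A per-element sigmoid gate is available behind `gating="sigmoid"` but is
  not the default.
* *Filter sharing.*  Each group owns its 7×7 filter bank.  The published
  parameter increments across g = 1, 4, 8, 16 (+0.001M/+0.002M/+0.003M)
  match 4 sites × g × (2·7² + 1) per-group parameters exactly; a single
  shared filter does not.

**Topology.**  Stages: root → 2 shield blocks (→64) → attention → pool → 4
blocks (→128) → attention → pool → 5 blocks (→192) → attention → pool → 4
blocks (→256) → attention → pool → global average pool → channel dropout
(rate 0.2, unstated in the source; configurable) → fully-connected 256→2.
The published table is internally inconsistent at the third shield stage
(its row lists 128 output channels while the following attention and block
rows consume 192); this implementation widens to 192 in the third stage's
first block, which is the only reading consistent with the later rows.

**Width multiplier.**  `width_multiplier=0.75` scales every stage width by
0.75, rounding to the nearest multiple of `g` (so all attention sites stay
divisible): channels 32, 64, 128, 192, 256 become 24, 48, 96, 144, 192.  The
16-filter stem is treated as a fixed property of the root module; only the
root's convolutional-branch width and the stage widths scale.  The
classifier input follows the last stage.

## Budget accounting and reconciliation

The profiler counts learnable parameters (convolution weights *and biases*,
batch-norm affine pairs, attention filters/biases, classifier) and
multiply-accumulates (convolutions at `H·W·k²·Cin·Cout`, divided by the
channel count for depthwise; `in·out` for the classifier; one MAC reported
as one FLOP, the lightweight-CNN convention).  Normalization, activations,
pooling, the fixed blur kernel, softmax and the element-wise attention
arithmetic are excluded by default; a switch (`count_elementwise=True`) adds
one op per output element for the alternative reading.  Batch-norm running
statistics are buffers, not parameters.

Three conventions above — biases counted alongside batch-norm, the
`round(C/t)` / `ceil(C/r)` channel splits, and the 52-wide root branch —
were fixed by reconciling against the published budget table rather than
taken from the block description, which does not specify them.  Under them
the module walk reproduces every published parameter budget at its printed
precision (default 400,249 → 0.400M; no-attention 398,665 → 0.399M; g = 1,
8, 16 → 0.399M, 0.402M, 0.405M) and the MAC budgets within 0.2–1.2%
(511.01 vs 512.06; 504.48 vs 505.26; 334.66 vs 338.64 for the 0.75×
variant).  One published number cannot be reconciled: the 0.75× variant's
0.23M parameters.  For any width multiplier applied uniformly, each layer's
MAC scale factor equals its parameter scale factor, so the overall parameter
ratio can differ from the MAC ratio only through spatial re-weighting; a
parameter ratio of 0.23/0.400 = 0.575 *below* the MAC ratio of
338.64/512.06 = 0.661 is unreachable for any structure that also reproduces
the 1.0× budgets (the depthwise/bias/affine terms scale linearly and floor
the parameter ratio near 0.61).  The implementation reports its computed
0.2447M and the reconciliation table itemizes the difference per layer.

## Synthetic seed benchmark

The generator emulates the structure of an industrial line-scan dataset:
100×100 RGB images, one object class against a dark background, near-balanced
classes.  "Normal" (label 1) is a single centered ellipse in seed-like tan
hues with randomized axis ratio, orientation and stripe texture.  "Abnormal"
(label 0) draws one of three archetypes with matched brightness statistics:
several smaller non-overlapping seeds in one frame, an irregular polygon
(stone/leaf analog) plus small impurity fragments, or a seed broken in two
plus fragments.  Additive Gaussian pixel noise (`noise_sd`, default 0.02 in
[0,1] units; 0 for the noiseless benchmarks) is applied last and clipped to
[0, 1].  Everything is a pure function of the spec, including its seed.

What this emulates — single-object-vs-clutter composition, class balance,
image geometry — and what it does not: real seed texture, illumination
variation, camera noise statistics, or the subtle phenotype differences
(e.g. haploid vs diploid embryo marks) that make real seed sorting hard.
Passing the learning tests therefore shows the architecture and training
recipe can fit and generalize on images of this structure at desk scale; it
does not certify real-data accuracy.

The ×4 augmentation is exact and loss-free: original, horizontal flip,
vertical flip, and a 90° rotation (the published recipe names "angle
rotation" without a value; 90° keeps the set closed under the pixel grid).
The stratified 75/25 split allocates `round(0.75·N)` training images overall
with per-class counts by largest remainder, so both splits stay balanced to
within one image.

## Training recipe

Mini-batch SGD: momentum 0.9, weight decay 1e-4, initial learning rate
0.001 multiplied by 0.1 after every 30 epochs (so epoch 31 runs at 1e-4),
cross-entropy on the raw two-way scores.  Unstated details resolved here:
the loss (cross-entropy is the standard for a two-way softmax head);
per-channel input standardization by the training split's mean/sd (stored
with checkpoints); He-normal weight init with a small-scale (σ = 0.01)
classifier so the initial loss sits at ln 2; batch-norm momentum 0.1.
Per-epoch history records the learning rate, mean batch loss, epoch-end
train accuracy in evaluation mode (dropout off, running statistics), the
within-epoch batch accuracy, and test accuracy.  All randomness (init,
shuffling, dropout) derives from explicit seeds; identical seeds give
identical histories.

### Problem sizes in the test suite

The learning checks run the full default architecture on the synthetic
benchmark at its native 100×100 resolution with batch 16: a 64-image
overfitting check (100% train accuracy within 30 epochs, early-stopped on
reaching it) and a 400-image 75/25 generalization check (≥90% test accuracy
within 8 epochs).  The network is fully convolutional up to the global
average pool, so input resolution is a free parameter; the 224 CenterCrop
path used for the published budgets is exercised by the profiling and shape
tests.  Unit-level training tests use a shallow single-stage variant at
32×32 to keep them fast.

## Numerical choices and edge cases

* Zero "same" padding for all convolutions (the 7×7 attention convolution
  included); edge replication only in the dense max; reflect padding only
  under the blur.  Borders therefore break the idealized "uniform descriptor
  → uniform attention" symmetry within 3 px of the frame — tests assert
  interior uniformity.
* Dense-max gradients route to the first window position attaining the
  maximum (ties are measure-zero for continuous inputs).
* Division-by-zero metrics (precision with no positive predictions, etc.)
  are NaN plus an `undefined` flag, never silently zero; ROC requires both
  classes and groups tied scores into one threshold step; AUC is trapezoidal
  and equals the normalized Mann–Whitney U statistic.
* Batch-norm in training uses biased batch variance and momentum-0.1 running
  updates; `eps = 1e-5`.
* All backward passes are verified against central finite differences in
  float64, including through the reflect-padding adjoint and the softmax
  gate.

## Known limitations

* Pure-NumPy training is single-threaded and memory-bound, which bounds
  desk-scale experiments to a few hundred images and tens of epochs.
  GPU-scale reproduction of real-data accuracy tables is out of scope.
* The 0.75× parameter budget discrepancy above is inherent to the published
  numbers, not a counting choice; no uniform-width reading removes it.
* The generator's classes are separable by object count plus shape; it is a
  benchmark for trainability and pipeline correctness, not a photorealistic
  seed simulator.
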