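# Methods

This note documents the models implemented in `odfcanet`, the conventions
behind the cost accountant, what the synthetic data generator does and does
not emulate, and the numerical choices that were genuinely open.

## Omni-dimensional dynamic convolution (ODConv)

A static convolution applies one kernel `W ∈ R^{c_out×c_in×k×k}` to every
input. An ODConv layer keeps a bank of `n` parallel kernels
`W_1 … W_n` and predicts, per input sample, four attention factors over the
kernel tensor's dimensions:

- `α_s ∈ (0,1)^{k×k}` — spatial positions of the kernel,
- `α_c ∈ (0,1)^{c_in}` — input channels,
- `α_f ∈ (0,1)^{c_out}` — output channels (filters),
- `α_w ∈ (0,1)^{n}` — the kernel index.

The attention head is: channel-wise global average pooling →
affine squeeze to `max(1, ⌊γ·c_in⌋)` units → ReLU → four parallel affine
heads with output sizes `k²`, `c_in`, `c_out`, `n` → element-wise sigmoid.
A `kernel_attention: softmax` option replaces the sigmoid on the kernel-index
head with a softmax over the `n` kernels (the normalization used by some
dynamic-convolution variants); the default is sigmoid on all four heads.

The per-sample effective kernel is the attention-modulated sum

    W_eff = Σ_i α_w[i] · (W_i ⊙ α_s ⊙ α_c ⊙ α_f),

each factor broadcast over the dimensions it does not index, and the layer
output is the ordinary cross-correlation of the sample with its own
`W_eff` (no convolution bias; batch normalization follows every convolution
in the residual blocks). Folding `α_c` into the kernel is mathematically
identical to modulating the input features; the implementation folds it into
the kernel so one fused primitive (`weighted_kernel_mix`) carries the whole
aggregation. With `n = 1` and all attention values clamped to 1 the layer
reduces exactly to a static convolution, which the tests exploit as a
degeneracy oracle.

Defaults: `n = 4`, `γ = 1/16`, squeezed width floored at 1. Both are
exposed in the YAML config under `odconv: {n, gamma, kernel_attention}`.

## Coordinate attention (CA) and feature coordinate attention (FCA)

Coordinate attention preserves positional information that global-pool
(SE-style) channel attention discards. The input `x ∈ R^{N×C×H×W}` is
average-pooled along width to a height profile `(N,C,H,1)` and along height
to a width profile `(N,C,1,W)`. The two profiles are concatenated along the
spatial axis, squeezed by a shared 1×1 convolution with channel-reduction
parameter `r` (batch normalization after the reduction is on by default,
`ca.bn_after_reduce`), passed through ReLU, split back, expanded per
direction by separate 1×1 convolutions, and gated by a sigmoid. The output
is `x ⊙ s_h ⊙ s_w` with both direction gates broadcast, so the output shape
equals the input shape and `|x̃| ≤ |x|` element-wise.

`r = 8` at every CA site by default. The reduction must satisfy
`⌊C/r⌋ ≥ 1`; violating it is a configuration error.

FCA aggregates CA-gated features from several depths: each tap is globally
average-pooled to a vector, linearly projected to the classifier width `D`,
and fused. The default fusion is a sum of the projected tap vectors with the
backbone's final pooled feature (which enters the sum unprojected when its
width already equals `D`); `fca.fusion: concat` concatenates instead. The
projection arithmetic is not uniquely determined by the source material;
affine projections on pooled vectors were chosen as the minimal reading, and
the widths are configurable.

## Network assembly

X-ODFCANet is a ResNet-18-style skeleton: a static 7×7 stride-2 stem
convolution + BN + ReLU + 3×3 stride-2 max pool, four stages of residual
basic blocks whose two 3×3 convolutions are ODConv layers (stem and 1×1
shortcut convolutions stay static), CA gates after stages 1–3 (the gated
output both continues down the backbone and is tapped for FCA), global
average pooling, FCA fusion, and an affine classifier to 3 logits. Softmax
is applied only inside the loss and at inference. At 224×224 input the four
stages produce 56/28/14/7 px feature maps.

### Cost accounting

`count_parameters` counts trainable scalars. `count_macs` counts one
multiply–accumulate per convolution tap (`H_out·W_out·c_out·c_in·k²`) and
per affine weight (`in·out`); pooling, normalization and element-wise
operations are free. For ODConv layers the per-sample attention head
(squeeze + four heads) and the kernel aggregation (`n·c_out·c_in·k²`) are
counted once per sample. CNN "FLOPs" tables conventionally report MACs
under this 1-FLOP-per-MAC convention; the package's ResNet-18/50/101
builders reproduce the widely quoted reference counts for those
architectures (within 1%), which pins the convention.

### The documented configuration

The reference design leaves `n`, `γ`, stage widths and projection widths
unstated, and its layer listing is internally inconsistent, so the
configuration behind its reported cost figures (4.45M parameters, 538.93M
MACs) cannot be read off directly. A search over the exposed configuration
space found that stage widths (32, 64, 128, 256) with blocks (1, 2, 3, 3),
a 32-channel stem, ODConv `n = 1`, `γ = 1/16`, CA `r = 8` and sum-fusion FCA
gives 4.416M parameters and 545.2M MACs — within 0.8% and 1.2% of the
published figures. This configuration is frozen in `configs/xodfcanet.yaml`.
Notably, `n = 1` (a single-kernel bank, with the four-dimensional attention
structure intact) is the only region of the space compatible with both
printed counts simultaneously: any `n ≥ 2` doubles the dominant kernel cost
without a matching MAC increase.

## Synthetic radiograph generator

The generator emulates only the gross appearance needed to exercise the
pipeline: a bright mediastinum background (170/255), two dark elliptical
lung fields (60/255) with jittered geometry, Gaussian pixel noise (σ = 8),
and three class recipes —

- **normal**: lung fields only;
- **pneumonia**: one focal bright consolidation (Gaussian blob, amplitude
  100, σ ≈ 9–12 px at 224) sampled well inside one lung field;
- **covid**: two to three diffuse low-contrast opacities (amplitude 45,
  σ ≈ 13–18 px) near the periphery of *each* lung — a bilateral pattern,
  deliberately distinct from the unilateral focal recipe.

The recipes are deliberately easy — an independent non-neural classifier
separates them almost perfectly — so that training-based checks are fast and
failures indicate pipeline defects rather than task difficulty. They do not
emulate ribs, projection physics, device heterogeneity, label noise, or
class imbalance; passing the training checks therefore says the pipeline
optimizes and evaluates correctly, not that the architecture would reach any
particular accuracy on real radiographs.

Splitting follows a 7 : 2 : 1 train/validation/test ratio by
largest-remainder apportionment (12,880 items split exactly into
9016/2576/1288), stratified per class when labels are supplied.
Preprocessing is minimal: grayscale, bilinear resize, scale to [0, 1],
replicate to 3 channels; per-channel standardization and horizontal-flip
augmentation exist but are off by default.

## Training and evaluation

Plain SGD with momentum 0.9 at a fixed learning rate (default 0.001, batch
32, 35 epochs — all configurable; "fixed" is honored by having no schedule).
The loss is softmax cross-entropy, `Loss = −Σ_i y_i log P_i` with natural
logarithm, computed from logits via max-subtracted log-sum-exp;
probabilities are clamped at 1e-12 before any explicit log. Runs are fully
seeded (initialization and data order), so identical seeds give bitwise
identical curves on CPU.

Because the engine trains with small batches, batch-normalization running
averages can sit far from the statistics the trained weights actually
produce, which depresses evaluation-mode accuracy. After each epoch the
trainer therefore recalibrates every BN layer by one exact-moment pass over
the training set with frozen weights (the same correction used after
stochastic weight averaging); `TrainConfig.bn_recalibrate` disables it.

Evaluation reports the K×K confusion matrix (rows = true class), per-class
precision `TP/(TP+FP)`, recall `TP/(TP+FN)` and specificity `TN/(TN+FP)`,
and mean accuracy `trace/total`. Zero-denominator cells are reported as NaN
("undefined"), never as 0. Cross-validation is stratified k-fold (default
k = 4) with a fresh seeded model per fold; folds are averaged by metric,
never by weights.

### Problem sizes used by the checked experiments

The training-based checks run a width-reduced configuration — stage widths
(16, 32, 64, 128), one block per stage, 16-channel stem, ODConv `n = 1`,
`γ = 1/4`, CA `r = 4` — on 50 synthetic images per class loaded at 64 px,
with lr 0.01, batch 16, 10 epochs, 4 folds. These sizes were chosen so the
whole cross-validation runs in a few minutes on one CPU core while still
exercising every layer type of the full architecture.

## Numerical choices and limitations

- All computation is float64 on a small reverse-mode autodiff engine written
  on numpy; convolution is im2col + BLAS matmul, with a per-sample-kernel
  variant for the dynamic convolution and a fused primitive for the
  attention-weighted kernel aggregation. Gradients of every primitive are
  verified against central differences.
- Attention sigmoids are mathematically in (0, 1) but saturate to exactly
  0.0/1.0 in floating point for |logit| ≳ 37; property tests bound input
  scales accordingly.
- `⌊c_in·γ⌋` is floored at 1 so extreme reductions stay well-defined.
- Max pooling breaks ties by first index (numpy argmax order).
- Undefined evaluation metrics propagate as NaN into JSON reports as null.
- Single-process CPU only; no data augmentation beyond an optional
  horizontal flip; no learning-rate schedules or early stopping by design.
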