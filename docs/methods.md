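# Methods

## Model

The network is a U-shaped encoder–decoder for binary segmentation. The
encoder applies `depth` levels of a double (3×3 convolution → batch
normalization → ReLU) block followed by 2×2 max pooling (stride 2), doubling
the channel width at each level from `base_channels`; a bottleneck block of
width `base_channels · 2^depth` sits at the bottom. Each decoder stage

1. up-samples the deeper tensor with a 2×2 stride-2 transpose convolution,
   halving its channels;
2. rescales the skip features with an additive attention gate driven by the
   up-sampled tensor (per-pixel scalar coefficient
   `α = σ(ψᵀ ReLU(Wxᵀx + Wgᵀg + b_g) + b_ψ)`, broadcast over channels);
3. concatenates gated skip and up-sampled tensor;
4. reduces the concatenation with a single 3×3 conv–BN–ReLU stage (a flag
   enables a second stage; one stage is the default because the block is
   meant to stay light);
5. runs a channel-attention path (squeeze-and-excitation) and a
   spatial-attention path (1×1 conv → BN → ReLU → 1×1 conv → sigmoid,
   stacked C times) in parallel on that tensor;
6. fuses them as `F = Fc ⊗ (Fs + 1)`. The `+1` guarantees the spatial mask
   only amplifies: `|F| ≥ |Fc|` element-wise.

Any of the three mechanisms can be disabled independently, giving the 8
ablation variants. A disabled channel path is the identity (`Fc` = features);
a disabled spatial path contributes `Fs = 0`, so the fusion algebra reduces
to the identity and the all-off variant is exactly a plain U-Net decoder
stage. The head is a 1×1 convolution to one channel plus sigmoid;
probabilities are thresholded at 0.5 (ties count as foreground, a fixed
convention so runs are deterministic).

Assumptions: RGB input, a single foreground class, input height and width
divisible by `2^depth` (the loader resizes to a configurable square size,
256×256 by default — divisible by 2⁴ and typical for dermoscopy-scale work).

## Attention details and open choices

* **Bias placement in the gate.** `Wx` carries no bias; the gate path `Wg`
  carries the bias vector `b_g` and the final projection `ψ` the scalar
  `b_ψ`. All three maps are 1×1 convolutions over channels.
* **Gate resampling.** When the gating signal lives on a coarser grid than
  the skip features it is resampled by bilinear interpolation
  (half-pixel-center convention). In this architecture the gate is taken
  after the transpose convolution, so the grids already match and no
  resampling occurs in practice.
* **Intermediate width.** `F_int = F_l / f_int_ratio` with `f_int_ratio = 2`
  by default — halving is the convention in the additive-attention-gate
  lineage and keeps the gate cheap. Configurable per network.
* **SE reduction ratio.** `r = 16` (the squeeze-and-excitation convention),
  clamped to `min(r, C)` so narrow test networks construct; after clamping
  `C` must be divisible by `r`, which holds for the power-of-two widths the
  encoder produces.
* **Spatial attention input.** Both attention paths read the *same* tensor —
  the output of the 3×3 convolution in step 4 — running in parallel, not in
  sequence.

## Loss, metrics, aggregation

The loss is mean per-pixel binary cross-entropy with predictions clipped to
`[1e-7, 1 - 1e-7]` before the logarithms (prevents −∞ at saturated sigmoid
outputs). The six metrics derive from pixel confusion counts; degenerate
denominators follow the standard challenge convention (empty ground truth and
empty prediction score 1.0 on SE/PC/F1/JS; claimed positives against an empty
ground truth score 0.0), so no metric is ever NaN. Dataset-level numbers are
per-image means by default — the common challenge convention — with pooled
pixel-count aggregation available behind a flag (`--pooled`); the two differ
whenever image difficulty varies, and neither is asserted to be the "true"
aggregate.

## Training recipe

AdamW with learning rate 2·10⁻⁴, β = (0.9, 0.999), batch size 8, 200 epochs —
these are the package defaults and a test pins them. Choices the recipe
leaves open, fixed here as package conventions: decoupled weight decay 10⁻²
(the optimizer's customary default, exposed in `TrainConfig`); constant
learning rate (no schedule); Kaiming-uniform initialization for all
convolutions and linear layers, seeded per network so construction is
reproducible; model selection by best validation F1 when a validation split
is supplied, otherwise the last epoch. Augmentation is the joint
horizontal/vertical flip with independent probability 0.5 per axis, applied
on the fly each epoch (equivalent in expectation to a pre-expanded dataset
and lighter on disk); test splits are never augmented. All randomness —
initialization, shuffling, augmentation — flows from explicit
`numpy.random.Generator` seeds, so two single-threaded CPU runs with one
config produce bit-identical logs.

## The autodiff engine

The network runs on a small reverse-mode automatic differentiation engine
written for this package (`ascunet.autodiff`): a `Tensor` records its parents
and a backward closure, and gradients propagate by reverse topological
traversal. Convolutions are computed as im2col + GEMM; the 2×2 stride-2
transpose convolution uses the non-overlap structure directly; max-pooling
ties break to the first element (deterministic); batch normalization keeps
float64 running statistics and uses batch statistics in training mode,
running statistics in eval mode (`eps = 1e-5`). The default parameter dtype
is float32 for speed; every layer accepts `dtype=float64`, which the oracle
tests use. Every primitive's gradient is verified against central finite
differences in the test suite.

## Synthetic data generator

`SynthSpec`/`generate_sample` emulate the difficulty factors of dermoscopy:

* **Lesion geometry** — a rotated ellipse whose boundary radius is modulated
  by a truncated random Fourier series (harmonics 2–5 only), scaled so that
  the maximum radial deviation equals `border_irregularity`. Low harmonics
  keep the blob star-shaped, hence a single connected component. Lesions are
  placed fully inside the frame; draws that cannot fit are redrawn, never
  truncated.
* **Low contrast** — the lesion region is tinted brown over a tan background,
  with the tint scaled by `contrast ∈ (0, 1]`; the tint's support equals the
  mask's support exactly, so mask and image never disagree.
* **Artifacts** — optional dark quadratic-Bézier hair strokes and a dark
  corner vignette are painted over the image only; Gaussian pixel noise
  (`noise_sd`, in [0,1] intensity units) is added last and the image is
  quantized to 8-bit PNG (the storage contract; tests compare
  post-quantization). The colors are documented constants, not dermoscopy
  statistics.

Generation is a pure function of `(spec, index)` via seed sequences, making
datasets byte-reproducible. Defaults: radius fraction 0.15–0.32 of the short
side, irregularity 0.25, contrast 0.5, hair probability 0.5, vignette
probability 0.3, noise σ 0.02 — moderate values that leave lesions visible
but non-trivial to delineate.

What the generator does **not** model: multi-component or ring lesions,
texture inside the lesion, color variegation, specular reflections, rulers
and gel bubbles, and the class mix of clinical archives. Passing tests on
this data demonstrate that the architecture, loss, optimization and metrics
are implemented correctly and can learn lesion-like segmentation; they say
nothing quantitative about performance on real dermoscopy archives.

## Validation problem sizes

The package's own validation runs use desk-scale configurations chosen once:
overfitting uses a depth-4 / base-8 network on 8 synthetic 64×64 samples for
at most 300 optimizer steps; the generalization check trains on 64 samples
and evaluates 16 held-out samples from the same distribution; the ablation
harness exercises all 8 variants at depth 2 / base 4 on 32×32 samples. The
full-size configuration (depth 4, base 64, 256×256) is the default for user
workflows on real data.

## Known limitations

* CPU-only: the autodiff engine targets correctness and desk-scale problems;
  full-resolution, full-width training on thousands of images is out of its
  intended range.
* Binary segmentation only; no deep supervision, no multi-class head.
* No pre- or post-processing (hair removal, color constancy,
  largest-component selection) — the evaluation measures the raw network
  output.
* `eval` and `predict` round the working resolution to the nearest multiple
  of `2^depth` and resize, which introduces interpolation error relative to
  native-size evaluation.
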