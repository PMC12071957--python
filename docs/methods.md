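# Methods

This note records the scientific and numerical choices behind `nucleiseg`:
the model, the canonical layer schedule and its parameter accounting, the
loss and metrics, the data pipeline conventions, what the synthetic
generator does and does not emulate, and the design decisions taken where
the design was genuinely open.

## Model and canonical schedule

The segmenter is an encoder–decoder U-Net specialized for binary nuclei
masks on grayscale input. The canonical configuration (`ArchConfig()`
defaults) is:

| stage | operator | resolution (in) | width |
|---|---|---|---|
| 1 | 3× conv3×3+ReLU (1→16) | 256 | 16 |
|   | max-pool 2×2 | 256→128 | 16 |
| 2 | 3× conv3×3+ReLU (16→32) | 128 | 32 |
|   | reduction block (n=2, depthwise) incl. pool | 128→64 | 32 |
| 3 | 3× conv3×3+ReLU (32→64) + residual block | 64 | 64 |
|   | max-pool 2×2 | 64→32 | 64 |
| 4 | 3× conv3×3+ReLU (64→128) + residual block | 32 | 128 |
|   | reduction block (n=2, depthwise) incl. pool | 32→16 | 128 |
|   | max-pool 2×2 | 16→8 | 128 |
| bridge | 3× conv3×3+ReLU (128→128) | 8 | 128 |

Five skip connections are taken at 256/128/64/32/16 (the deepest one after
the second reduction block); the decoder mirrors with five blocks of
[nearest ×2 upsample → concat skip → 3× conv3×3+ReLU] at widths
128/64/32/16/16 and a 1×1 conv + sigmoid head. Spatial attention gates the
two deepest skips (16² and 32²).

**Parameter accounting.** Every layer has a closed-form count
(k²·C_in·C_out + C_out for convs, 9C + C depthwise, 2C per batch norm,
k²·2 + 1 per attention gate); the table sum must equal the engine's count
exactly, and the test suite enforces this integer equality for every
variant. The canonical full model totals **2,214,703** trainable scalars
(2.2 M); the classic baseline U-Net variant (widths 32/64/128/256, 512
bridge, two convs per block, 2×2 transposed-conv upsampling) totals
**7,759,521** (7.8 M). Published descriptions of closely related
architectures quote 2.3 M for a model of this type while describing an
attention module whose stated form has only 99 parameters; our accounting
is the auditable one — any such ~0.1 M gap is most plausibly a heavier
attention head than the one described, and we implement the described one.

**Ablation variants** (`assemble_variant`):

- `no_residual` — residual blocks removed (−369,792).
- `no_attention` — attention gates removed (−198).
- `no_reduction` — each reduction block replaced by one channel-preserving
  3×3 conv + pool (2,349,015 total).
- `no_depthwise` — each complexity-reduction stage reverts to a classic
  two-standard-3×3-conv + pool stage at full width (2,505,847), i.e. the
  counterfactual network built without the depthwise-separable bottleneck
  idea at all. A narrower reading — swapping only the bottleneck's depthwise
  conv for a standard conv at width C/n² — changes a mere ~9.4 k parameters
  and would make "without depthwise" cheaper than "without reduction",
  inverting the cost ordering the ablation is meant to exhibit; that
  narrower swap remains available via `ArchConfig.use_depthwise = False`.
- `baseline_unet` — the classic reference model above.

This yields the strict ordering
`no_attention < full < no_reduction < no_depthwise < baseline_unet`.

Residual blocks place the identity addition after the second conv–BN–ReLU
unit, so zero-initialized convolutions make the block an exact identity.
Batch normalization is used only inside residual blocks; all other
convolutions are bare conv+ReLU, which keeps the parameter accounting
simple and reproducible.

## NumPy network engine

The layers live in `nucleiseg.engine`: stride-1 same-padding convolutions as
im2col + GEMM, depthwise convolutions via sliding windows, 2×2 max-pool with
first-occurrence tie-breaking, nearest upsampling, 2×2/stride-2 transposed
convolutions, batch norm with running statistics (momentum 0.1, eps 1e-5),
and the attention gate. Each operator implements an explicit backward pass;
the test suite validates all of them against central finite differences at
float64. Weights are He-uniform initialized (limit √(6/fan_in)) from a
generator seeded by `ArchConfig.seed`; biases start at zero. Training runs
in float32; the optimizer is Adam (β₁ 0.9, β₂ 0.999, eps 1e-8), default
learning rate 1e-3, batch size 8 — conventional defaults, recorded in the
config so results are auditable.

## Loss and metrics

Hybrid loss `α·BCE + (1−α)·(1 − softDice)` with α = 0.5; probabilities are
clamped at 1e-7 inside the BCE term and the soft-Dice uses smoothing
ε = 1e-6. Per-sample weights (inverse stratum frequency, mean 1) multiply
both terms.

Metrics are computed on exact integer pixel counts with no smoothing.
Conventions for degenerate inputs: empty-vs-empty mask pairs score DSC =
IoU = 1 (nothing to find, nothing found) and are flagged in the report;
zero-denominator precision/recall/F1 return 0 with a degeneracy flag.
Probability maps are binarized at 0.5 before scoring. The Dice–Jaccard
identity IoU·(2−DSC) = DSC holds exactly on integer counts and is
property-tested.

Two figure-of-merit readings exist because the pixel-count form
TP/(TP+FP+FN) is identical to IoU, yet the statistic is conventionally
reported as a distinct precision/recall-balanced score; the default report
uses FoM = PR/(P+R−PR) and labels the mode (`fom_mode`), with the literal
pixel-count form available as `figure_of_merit`.

Object-level detection matches predicted to true instances greedily in
descending IoU order (ties: lower ground-truth index, then lower prediction
index); a nucleus is detected iff its match exceeds IoU 0.5 strictly. For
disjoint instance sets at threshold 0.5 the IoU>0.5 graph is itself a
one-to-one matching (two disjoint objects cannot both claim more than half
of one prediction), so the greedy result coincides with the exhaustive
optimum; the suite checks this against a brute-force oracle for up to four
objects per side. Predicted instances are obtained from the binary mask by
connected-component labeling.

## Data pipeline conventions

- **Layout**: one folder per image id with `images/` and `masks/`
  subfolders; one binary PNG per nucleus; overlap between instance masks is
  a validation error naming the image id. Trees without `masks/` load as
  unlabeled records.
- **RLE dialect**: 1-based, column-major, space-separated (start, length)
  pairs with strictly increasing non-overlapping runs — the Data Science
  Bowl submission convention; `decode(encode(m)) = m` is property-tested.
  Submission CSVs use the `ImageId,EncodedPixels` header.
- **Normalization**: luminance grayscale conversion, bilinear resize to the
  configured square size (nearest-neighbour for masks, keeping them
  binary), global histogram equalization (CLAHE intentionally not applied;
  `equalize=False` opts out), then min–max to [0, 1]. Constant images
  degenerate to all zeros with a warning. The default working resolution is
  256×256 (training at 96×96 is used for desk-scale runs; both satisfy the
  ÷32 constraint).
- **Mask refinement**: morphological opening then closing with a disk of
  radius 1, intended for speck/inconsistency repair; idempotent.
- **Splitting**: per-stratum shuffled largest-remainder allocation to
  train/validation/test (default 0.8/0.1/0.1), exact partition, per-stratum
  proportions within one sample; stratified 5-fold CV via scikit-learn's
  `StratifiedKFold` (seeded, falling back to unstratified folds with a
  warning when a stratum is smaller than k). The stratum key is the
  (polarity, density-tercile) label for synthetic data, standing in for the
  modality/cell-type grouping of real collections.
- **Augmentation**: horizontal/vertical flips, 90° rotations, ±10%
  multiplicative intensity jitter, and an optional small affine warp
  (rotation ≤10°, scale 0.95–1.05) applied identically to image and mask;
  all draws come from one seeded generator, so replays are bit-identical.

## Synthetic scenes

The generator emulates the axes of variability that matter to this model
family: instance density, size and eccentricity, crowding (via
`overlap_pressure`, which relaxes the center-separation requirement;
contended pixels go to the nearer center so masks stay disjoint by
construction), both intensity polarities, Gaussian blur and sensor-like
Gaussian noise. It does **not** emulate nuclear texture, stain chemistry,
uneven illumination, or out-of-focus artifacts — so green tests demonstrate
mechanical correctness and learnability of the pipeline and model, not
clinical-grade performance on real histopathology. Default conditions
(256×256, 8–24 nuclei of semi-axis 6–16 px, pressure 0.3, blur σ 1 px,
noise σ 0.05) are fixed once; `scaled_default_spec` shrinks the geometry
proportionally for smaller rasters.

## Training protocol and problem sizes

Runs are fully deterministic functions of (seed, config, data). The
monitored quantity is validation Dice when a validation set is supplied,
else training Dice; the best state is checkpointed and restored, with early
stopping after 20 stale epochs by default. Non-finite loss aborts with a
learning-rate diagnostic. Note the training-Dice curve is accumulated from
the forward passes of each epoch (batch statistics for batch norm), while
`predict`/`score` use running statistics, so the two can differ by a small
margin near convergence.

Desk-scale sizes used throughout the tests: 96×96 images for the capacity
check (training the full model on 8 synthetic scenes reaches Dice ≥ 0.9
within ~60 epochs, about two minutes on one CPU core) and 32×32 for
determinism and plumbing checks; the ablation harness reports parameter
counts always and trains only when explicitly given records and a training
config. These sizes were chosen as the smallest that exercise all five
resolution levels of the architecture.

## Known limitations

- The NumPy engine targets clarity and testability; it is single-device,
  eager, and roughly an order of magnitude slower than GPU frameworks, so
  full-scale (256×256, thousands of images) training is out of scope here.
- `no_depthwise` embodies a counterfactual-architecture judgment (see
  above); both readings are constructible and the choice is recorded.
- Object matching assumes disjoint instances within each set, per the
  dataset's no-overlap rule; soft or overlapping instances are rejected.
- The histogram-equalization step is global; strongly vignetted real images
  would need local normalization that is deliberately not included.
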