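# nucleiseg

A toolkit for **nuclei instance segmentation** in 2-D microscopy images,
built around a lightweight attention U-Net. It is aimed at image-analysis
practitioners who want a parameter-efficient segmentation network whose
every architectural ingredient is ablatable and whose every reported number
is reproducible from code: the architecture builder exposes exact
closed-form parameter accounting, the data pipeline speaks the 2018 Data
Science Bowl folder layout and run-length-encoded submission dialect, and a
seeded synthetic nuclei generator makes the whole stack testable without
downloading any external data.

## The model

The network is a U-Net whose encoder trades parameters for structure:

- **Stage conv blocks** — three 3×3 same-padding convolutions with ReLU per
  stage, widths 16/32/64/128, with a 128-wide bridge at 1/32 resolution
  (input 256×256 → bridge 8×8).
- **Complexity-reduction blocks** (ShuffleNet-style), used for two of the
  five downsamplings: two 1×1 channel reductions (each dividing width by
  *n* = 2), a depthwise 3×3 convolution at width C/n², two 1×1 expansions
  back to C, then a 2×2 max-pool. For C = 128 this costs 21 088 parameters
  where a single standard 3×3 C→C convolution costs 147 584.
- **Residual blocks** at the two deepest encoder stages: two 3×3
  convolutions with batch normalization and ReLU, plus an identity shortcut.
- **Spatial attention** on the two deepest skip connections: channel-wise
  mean and max maps, concatenated and passed through one 7×7 convolution and
  a sigmoid to gate the skip (99 parameters, independent of channel count).
- **Decoder** — parameter-free ×2 nearest upsampling, skip concatenation,
  three 3×3 convolutions per block; 1×1 convolution + sigmoid head.

Training minimizes the hybrid loss

    L = α · L_BCE + (1 − α) · L_Dice,    α = 0.5,

where `L_Dice = 1 − (2|P∩G| + ε)/(|P| + |G| + ε)` on soft predictions.
Evaluation covers Dice (DSC), Jaccard/IoU, pixel accuracy,
precision/recall/F1, the figure of merit, and object-level detection (a
nucleus counts as detected when matched one-to-one with IoU > 0.5).

The network runs on a small NumPy engine included in the package (im2col
convolutions, explicit backprop, Adam), so the only heavy dependency is
BLAS; gradients are verified against finite differences in the test suite.

## Worked example

```python
import numpy as np
from nucleiseg import ArchConfig, assemble_variant, count_parameters
from nucleiseg.synthetic import SceneSpec, render_scene
from nucleiseg import UNetSegmenter

# exact parameter accounting of the full model and the classic baseline
for variant in ("full", "baseline_unet"):
    n = count_parameters(assemble_variant(ArchConfig(), variant))
    print(f"{variant:>14}: {n:,} parameters ({n/1e6:.1f} M)")

# overfit eight 96x96 synthetic scenes (both intensity polarities)
recs = [render_scene(SceneSpec(image_size=96, n_instances=(4, 10),
                               axis_range=(4, 9), seed=100 + i,
                               polarity="bright_on_dark" if i % 2 == 0
                               else "dark_on_bright"))
        for i in range(8)]
X = np.stack([r.image for r in recs]).astype(np.float32)
y = np.stack([r.merged_mask for r in recs]).astype(np.float32)
est = UNetSegmenter(epochs=200, seed=0, patience=10**6, early_stop_dice=0.93)
est.fit(X, y)
print(f"train Dice after {est.n_epochs_run_} epochs: {est.score(X, y):.3f}")
```

prints

```
          full: 2,214,703 parameters (2.2 M)
 baseline_unet: 7,759,521 parameters (7.8 M)
train Dice after 60 epochs: 0.909
```

i.e. the full model uses ~3.5× fewer parameters than the classic U-Net at
half width, and has enough capacity to interpolate a small training set to
Dice ≈ 0.9 in a couple of minutes on one CPU core.

The same flows are scriptable from the shell:

```bash
nucleiseg synth --n-images 16 --out data/train --seed 7
nucleiseg train --data data/train --input-size 96 --epochs 40 --checkpoint model.npz
nucleiseg eval  --data data/train --checkpoint model.npz --out report
nucleiseg params --variant full          # layer table + parameter count
nucleiseg ablate --out ablation.csv      # all six variants
```

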