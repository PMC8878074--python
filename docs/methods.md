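# Methods

## Model

The segmentation network is a four-level encoder–decoder for single-channel
microscopy images whose side is a multiple of 16.  All downsampling is
anti-aliased ("blur pooling"): a dense stride-1 2×2 max, a separable
binomial low-pass filter, then subsampling.  The three design conventions
that the idea leaves open are fixed as follows and used consistently by the
numpy reference functions, the differentiable layers, and the tests:

- the dense 2×2 max is anchored top-left and edge-padded on the bottom and
  right, so its output keeps the input size;
- the low-pass filter is reflect-padded (mirror without repeating the edge
  sample); when a pad would reach the axis length (1–2 px maps deep inside
  the pyramid module) it degrades to symmetric padding so the operation
  stays defined and still preserves constants;
- subsampling starts at index 0 (top-left), output side = ceil(in/stride).

The binomial kernel side defaults to 3 (`[1,2,1]` row).  The stride-1 "blur
convolution" (C1 and the pyramid branches) applies the low-pass filter even
though it does not subsample; this keeps C1 consistent with the strided
variants (an open choice — the alternative reading is a plain convolution).

**Blur attention.**  Each DN block refines its features with a channel gate
and a spatial gate.  The channel gate pools each channel two ways — global
average, and repeated stride-2 blur max pooling down to 1×1 (maps are first
reflect-padded to the next power of two so the descent is well defined on
any size) — passes both descriptors through one shared two-layer MLP (ReLU
hidden layer, reduction ratio r = 8) and takes the sigmoid of the sum.
The spatial gate collapses channels by mean and by max; the max plane is
low-pass filtered (blur pooling degenerates to its filtering step when no
resolution change is wanted), the two planes are stacked and filtered by a
learned 3×3 convolution (3×3 exactly, not the 7×7 some attention designs
use), and the sigmoid gates every pixel.  Both gates are computed from the
block's incoming features and applied in channel-then-spatial order,
`(M_cb ⊗ F) ⊗ M_sb`.

**Channel schedule.**  C1 produces `base_channels` (default 32); each DN
block doubles the width with a 3×3 convolution + ReLU before attention,
capped at `8 × base_channels` (so 32 → 64 → 128 → 256 → 256).  The cap
keeps the full-size model at ≈5.1 M parameters; uncapped doubling would
more than double that budget, dominated by the pyramid-module branch
convolutions at the widest concatenations.  Decoder widths halve back down
with a floor of `base_channels`; auxiliary branches all carry
`base_channels`.

**Pyramid blur pooling (PBP).**  Before each transpose convolution, the
decoder input (concatenation of the upsampled stream, the matching DN
output and the matching auxiliary map) passes a four-branch pyramid.  Each
branch anti-alias-pools the map to a bin×bin grid (bins 1, 2, 4, 8; a bin
larger than the map clamps to the map side; non-dividing sides are
reflect-padded to `bin · 2^k` and pooled by repeated halving so every step
keeps the dense-max + low-pass semantics), applies a 3×3 convolution with
dilation equal to the bin (zero-padded — dilated taps necessarily leave
tiny grids), a ReLU and the low-pass filter, and is resampled back to the
input size by nearest neighbour (bit-reproducible).  The input is
concatenated with the four `C/4`-channel branches: C in, 2C out.  The
pyramid is applied before the transpose convolution, i.e. at the resolution
whose context it summarizes.

**Decoder head.**  Each UP block ends in a 3×3 stride-2 transpose
convolution (implemented as zero-stuffing + valid convolution, exactly
doubling the side) with ReLU; a 1×1 convolution + sigmoid produces the
foreground probability map.  Instances are 8-connected components of the
thresholded map (threshold 0.5, components under 4 px dropped, labels
assigned in raster order).  No watershed or other splitting post-processing
is applied, a deliberate scope choice with consequences discussed under
limitations.

## Training

The loss is binary cross-entropy plus (1 − soft Dice) with equal weights —
the Dice term counteracts foreground/background imbalance, BCE keeps
per-pixel gradients informative.  Optimization is Adam (lr 1e-3, batch 8),
early stopping on validation loss with patience 10, best-validation
checkpoint restored at the end.  The corpus is split 80/20 into train and
validation by a seeded permutation; initialization, splits and batch order
all derive from explicit seeds, so runs are bit-reproducible.  The
pretrain + fine-tune schedule trains first on a surrogate corpus (by
default synthetic fluorescence scenes) and continues on the target corpus
from the pretrained weights, with both phases logged separately.

The network and optimizer run on the package's own reverse-mode autodiff
engine (`cbaseg._tensor`): float32 forward/backward, gradients checked
against central differences in the test suite.  Convolution is implemented
as nine shifted tensor contractions; transpose convolution as zero-stuffing
plus valid convolution; all gather-style operations (padding, nearest
resampling, subsampling) scatter-add their gradients.

## Preprocessing

`normalize_image` converts to luminance (ITU-R 601 weights), resizes
bilinearly to the network side (192 by default) and rescales to [0, 1]; it
is idempotent.  `wavelet_lowpass` runs a one-level 2-D DWT with a
biorthogonal wavelet (bior1.3 by default — the sub-family and threshold
rule are open choices), soft-thresholds the detail subbands at the
universal threshold `σ̂ √(2 ln N)` with `σ̂` estimated from the median
absolute deviation of the diagonal band, and inverts; when enabled in the
training pipeline it runs after grayscale conversion and before resizing,
so the noise estimate sees the native pixel grid.  It is off by default in
the synthetic studies, whose noise level is a controlled condition.
`tile_image` cuts slides into non-overlapping patches (250 px default;
1000×1000 → 16 patches), reflect-padding non-divisible sides and
relabelling each mask patch contiguously; reassembly is exact.
`augment_stream` yields an endless seeded stream of rotations (axis-aligned
plus optional free-angle with nearest-neighbour masks), flips and random
crops; a fixed-size epoch (e.g. 2372 crops from 536 sources) is a
configuration preset.

## Synthetic scenes

The generator renders elliptical nuclei with exact instance labels.
Placement is rejection sampling with two regimes: isolated placements keep
at least one background pixel of separation; with probability
`cluster_prob` a nucleus is seeded against an existing one and may touch it
(small overlaps are trimmed; contested pixels stay with the earlier
nucleus), so `cluster_prob` directly controls the touching-nucleus rate.
Fluorescence mode renders bright nuclei (intensity U(0.55, 0.95)) on a dark
background (0.08) under a smooth multiplicative illumination field (±25%
by default) with Gaussian read noise (σ = 0.03) and optional Poisson
scaling; histology mode renders hematoxylin-like purple nuclei on an
eosin-like pink textured RGB background by fixed linear colour mixing — a
synthetic stand-in, not a stain-physics model.  Rasterization uses the
centre-in-pixel convention with hard (non-anti-aliased) edges so labels are
exact.

What the scenes do not emulate: optical point-spread blur, chromatic
aberration, out-of-focus debris, intensity texture inside nuclei, real
stain variability, and overlapping (not merely touching) nuclei.  Passing
the studies therefore demonstrates that the architecture, training loop and
evaluation are correct and that the model can learn this family of
segmentation problems — not clinical-grade performance on real corpora.

## Study conditions

All reference experiments live in `cbaseg.experiments` and are shared
verbatim by the test suite and `scripts/acceptance.py`; problem sizes were
chosen so the whole suite runs on one CPU core in minutes.

- **Architecture arithmetic** runs the real blocks at width 4 and records
  the side sequence (192 → 96 → 48 → 24 → 12, auxiliaries 96/48/24,
  decoder output 192).
- **Tiling arithmetic** generates 30 + 14 synthetic 1000×1000 slides and
  tiles them into 250-px patches (16 per slide: 480 and 224).
- **Shift consistency** compares mean L2 drift of blur max pooling versus
  plain stride-2 max pooling under 1-px circular shifts of 100 random
  32×32 images.
- **End-to-end study**: 200 fluorescence scenes at 64×64 (4–10 nuclei,
  radius 4–9 px, cluster probability 0.1), reduced network (base width 8),
  10 epochs, fixed seed; 20% held out.  The mostly-isolated regime is
  deliberate: with connected-component instance extraction, even a perfect
  probability map scores only ≈0.65 AJI when a quarter of nuclei touch
  (≈0.79 at 10%), so object-level evaluation of a semantic-mask pipeline is
  informative only when touching is the exception — which is also the
  regime of the fluorescence corpora this family emulates.  Under these
  conditions the study reaches held-out DSC ≈ 0.96 and AJI ≈ 0.57.
- **Pretraining study**: per seed, a 12-scene target corpus (32×32, higher
  noise, stronger illumination, smaller nuclei) is fit either directly for
  8 epochs or for 4 epochs after 4 epochs of pretraining on a 40-scene
  surrogate corpus of the cleaner style; validation Dice is compared over
  five seeds.  Base width 8 is used here because width-4 models
  occasionally plateau within the short budget, which would add
  uninformative zero-zero comparisons.

## Numerical choices and degenerate inputs

- Low-pass kernels are validated to unit sum (1e-12); DC preservation is
  asserted to 1e-6 in float32 paths.
- Sigmoid is computed in its numerically stable split form; logarithms are
  clamped at 1e-7; the soft-Dice denominator carries +1e-6.
- Elementwise-max gradients route ties to the first argument; axis-max
  gradients split ties equally.
- A wavelet threshold of zero (noise-free input) skips thresholding
  entirely rather than dividing by zero.
- AJI matching consumes predictions one-to-one (a prediction matches at
  most one ground-truth nucleus); ties break to the lowest predicted
  label; a ground-truth nucleus with no overlapping unused prediction adds
  its full area to the denominator.  Dataset-level AJI defaults to the
  unweighted per-image mean, with pooled accumulation exposed as an option.
- Empty-vs-empty masks score 1.0 for Dice and AJI; precision (recall) is
  1.0 when there are no predicted (true) positives.

## Known limitations

- Connected-component instance extraction cannot split touching nuclei; in
  dense or clustered tissue the AJI ceiling drops well below what boundary
  quality alone would allow.  A marker-based splitting step would lift
  this, but is outside the method's scope.
- The autodiff engine is single-threaded numpy; the full 192-px, 5.1 M
  parameter configuration is practical for inference and short fine-tuning
  but not for large-scale training.
- Free-angle rotation resamples masks with nearest neighbour; very thin
  instances can lose pixels (axis-aligned transforms are exact).
- Histology colour mixing is illustrative; no stain normalization is
  provided or attempted.
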