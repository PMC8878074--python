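# cbaseg — convolutional blur attention network for cell-nucleus segmentation

Accurate nucleus segmentation in microscopy images is a prerequisite for
cell counting, phenotyping and downstream diagnostics, but nuclei come in
many sizes and stains, under uneven illumination, and often touch one
another.  `cbaseg` implements a convolutional blur attention (CBA)
encoder–decoder for this task, together with everything needed to exercise
it end to end on a laptop CPU: anti-aliased pooling primitives, object-level
evaluation, preprocessing, a seeded synthetic nuclei-scene generator, and a
training pipeline with an optional pretrain + fine-tune schedule.  The
network and its training loop run on a compact numpy autodiff engine that
ships with the package, so there is no deep-learning-framework dependency.

## The model

**Blur pooling.**  Ordinary max pooling aliases: a one-pixel shift of the
input can change which samples survive subsampling.  Blur pooling
decomposes pooling into a dense (stride-1) 2×2 max, a normalized binomial
low-pass filter *k* (default 3×3, `[1,2,1]ᵀ[1,2,1]/16`), and subsampling:

    BlurPool(F) = (k * MaxPool₁(F)) ↓ s

Because the low-pass filter removes the frequencies subsampling would fold
back, pooled features drift far less under small shifts (measured directly
by the shift-consistency experiment below).

**Blur attention.**  A CBAM-style refinement in which one pooled descriptor
path is replaced by blur pooling:

    M_cb = σ( MLP(AvgPool(F)) + MLP(BlurPool(F)) )        — channel gate
    M_sb = σ( f³ˣ³[ AvgPoolᶜ(F) ; BlurPoolᶜ(F) ] )        — spatial gate
    F_out = (M_cb ⊗ F) ⊗ M_sb

with a shared two-layer MLP (reduction ratio r = 8) and ⊗ element-wise
multiplication.

**Architecture.**  A stride-1 blur convolution (C1) lifts the input, four
DN blocks (3×3 convolution doubling channels, blur attention, stride-2 blur
max pooling) encode it — for a 192×192 input the sides run
192 → 96 → 48 → 24 → 12 — and four UP blocks decode it, each applying a
pyramid blur pooling module (parallel anti-aliased pooling to 1×1, 2×2,
4×4 and 8×8 grids with dilated 3×3 blur convolutions, resampled and
concatenated) before a 3×3 stride-2 transpose convolution.  Auxiliary blur
convolutions at strides 2/4/8 re-extract the C1 features at sides 96/48/24
and join the skip connections.  A 1×1 convolution + sigmoid yields the
foreground probability; instances are connected components of the
thresholded map.  The default configuration holds ≈5.1 M parameters.

**Metrics.**  Pixel level: DSC = 2|A∩B|/(|A|+|B|), precision, recall, F1.
Object level: the aggregated Jaccard index,

    AJI = Σᵢ |Gᵢ ∩ Pᵢ| / ( Σᵢ |Gᵢ ∪ Pᵢ| + Σ_rest |P| )

where each ground-truth nucleus Gᵢ greedily consumes the unmatched
prediction with the highest Jaccard overlap and every unmatched prediction
inflates the denominator — over- and under-segmentation both lower AJI.

## Worked example

Train a reduced model (32×32 inputs, base width 8) on synthetic
fluorescence scenes and score held-out scenes:

```python
from cbaseg import (NetworkConfig, build_cba_network, TrainConfig, train,
                    predict, evaluate_pair)
from cbaseg.pipeline import synthetic_corpus

scenes = synthetic_corpus(60, 32, seed=0, n_range=(2, 5),
                          radius_range=(3.0, 6.0), cluster_prob=0.1)
model = build_cba_network(NetworkConfig(input_size=32, base_channels=8),
                          init_seed=0)
model, history = train(model, scenes[:48],
                       TrainConfig(epochs=16, batch_size=8, seed=0))
print(f"final val loss: {history['val_loss'][-1]:.3f}")
for img, labels in scenes[48:52]:
    prob, pred = predict(model, img)
    r = evaluate_pair(labels, pred)
    print(f"nuclei: {labels.max():2d}  found: {pred.max():2d}  "
          f"dsc={r.dsc:.3f}  aji={r.aji:.3f}")
```

Output (≈30 s on one CPU core):

```
final val loss: 0.206
nuclei:  5  found:  2  dsc=0.911  aji=0.294
nuclei:  3  found:  1  dsc=0.918  aji=0.189
nuclei:  2  found:  2  dsc=0.929  aji=0.867
nuclei:  5  found:  3  dsc=0.910  aji=0.452
```

Pixel-level Dice is already high after a one-minute training run, while AJI
is much stricter: whenever touching nuclei merge into one connected
component, the unmatched ground-truth nuclei and the inflated union push
the score down.  At the package's full study scale (64×64 scenes, 200
images, 10 epochs) the held-out means reach DSC ≈ 0.96 and AJI ≈ 0.57.

The same workflow is available from the shell:

```bash
cbaseg generate --out corpus --n 30 --size 256 --seed 0
cbaseg train --data corpus --pretrain synthetic --out model.npz
cbaseg predict --model model.npz --images corpus --out preds
cbaseg evaluate --pred preds --truth corpus --out metrics.csv
cbaseg tile --images slides --masks slides --patch 250 --out patches
```

## Layout

| module | contents |
| --- | --- |
| `cbaseg.blur_ops` | binomial kernels, blur filtering/downsampling, blur max pooling, blur convolution |
| `cbaseg.attention` | channel/spatial blur attention and their composition |
| `cbaseg.network` | DN/UP blocks, pyramid blur pooling, the assembled network, checkpoints |
| `cbaseg.preprocess` | grayscale normalization, wavelet denoising, tiling, augmentation |
| `cbaseg.metrics` | DSC, precision/recall/F1, AJI, instance extraction, CSV reports |
| `cbaseg.synth` | seeded fluorescence/histology scene generator with exact labels |
| `cbaseg.pipeline` | training (pretrain + fine-tune), tiled prediction, corpus evaluation |
| `cbaseg.experiments` | the canonical desk-scale studies used by tests and the reproduction script |
| `cbaseg._tensor`, `cbaseg.nn` | the numpy reverse-mode autodiff engine and layers |
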