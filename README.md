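# patchrefine

Two-stage coarse-to-fine **binary semantic segmentation** with
uncertainty-guided patch refinement.

A first model segments a downscaled version of the image. The upscaled
probability map is split into a grid of contiguous patches; each patch is
scored by the mean per-pixel uncertainty of the coarse probabilities, and
patches scoring above a threshold are re-segmented at full resolution by a
second model whose output replaces the coarse prediction inside those
patches. The second model is optionally initialized from the first
(fine-tuning) and receives the first model's penultimate activation as
context via elementwise addition. During stage-2 training, one patch per
image per epoch is sampled by a `random`, `weighted`, or `highest`
uncertainty strategy.

Everything runs on CPU with NumPy: the default `tiny` backbone is a small
fully convolutional encoder-decoder (~19k parameters) trained with focal
loss and Adam, with hand-written backprop that is gradient-checked in the
test suite. The heavyweight backbones (ResNet-50-encoder FCN, DeepLab v3,
U-Net, SegNet) are represented analytically for exact parameter and FLOP
(multiply-accumulate) accounting; running them would require a GPU
deep-learning runtime and is out of scope.

## Uncertainty variants

Two pixel-uncertainty functions are available. The default,
`full_entropy`, is binary Shannon entropy, symmetric and maximal at
p = 0.5. The alternative `paper` variant is `u(p) = -p*log2(p)`, which
peaks at p = 1/e and is asymmetric; it is retained for comparison.
Selection thresholds are always interpreted on a [0, 1] scale normalized by
the variant's maximum, so threshold 1 refines nothing and threshold 0
refines every patch under either variant.

## CLI

```bash
# generate a synthetic dataset (cell-like blobs, spatially heterogeneous
# difficulty) plus a CSV manifest with a 70/30 train/test split
patchrefine synth --out data --n 100 --size 96 --seed 0

# stage 1: train the coarse model on 4x-downscaled whole images
patchrefine train-stage1 --manifest data/manifest.csv --out m1.npz \
    --size 96 --patches 16 --epochs 20 --lr 2e-3 --seed 0

# stage 2: train the refinement model on sampled full-resolution patches
patchrefine train-stage2 --manifest data/manifest.csv --m1 m1.npz \
    --out m2.npz --size 96 --patches 16 --strategy weighted \
    --finetune --context --epochs 20 --lr 2e-3 --seed 0

# two-stage inference on one image (16-bit PNG probability map)
patchrefine predict --image data/images/img_0070.png --out prob.png \
    --m1 m1.npz --m2 m2.npz --patches 16 --threshold 0.25

# test-split evaluation: per-image and mean Dice, refinement fraction,
# analytic FLOP cost
patchrefine evaluate --manifest data/manifest.csv --report report.json \
    --m1 m1.npz --m2 m2.npz --patches 16 --size 96 --threshold 0.25

# parameter / FLOP table across input sizes
patchrefine count-ops
```

Every command takes `--config file.yaml` with flag overrides, and training
commands write their fully resolved configuration and a JSON-lines loss log
next to the checkpoint.

To use real data instead of the generator, write a CSV manifest with header
`image,mask,split` (split is `train` or `test`), pointing at 8-bit
greyscale/RGB images and binary mask PNGs (any nonzero pixel is foreground).

## Layout

- `src/patchrefine/grid.py` — patch grids, crops, write-back, bilinear /
  nearest resizing
- `src/patchrefine/uncertainty.py` — pixel uncertainty, patch scores,
  selection and sampling
- `src/patchrefine/models/` — SegModel contract, tiny NumPy backbone,
  analytic op counting
- `src/patchrefine/pipeline.py` — two-stage inference, Dice, evaluation
- `src/patchrefine/training.py` — focal loss, augmentation, stage-1/2
  training, cross-stage transfer
- `src/patchrefine/synthetic.py` — seeded heterogeneous-difficulty fixture
  generator
- `src/patchrefine/io.py`, `src/patchrefine/cli.py` — manifests, image I/O,
  run configs, CLI
- `src/patchrefine/bench.py` — the desk-scale benchmark used by the
  acceptance tests
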