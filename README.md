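# grainseg

Instance segmentation of densely packed, adherent wheat kernels.

## The problem

Wheat quality grading needs a count of *unsound kernels* — grains that are
damaged but still usable: moldy, injured (insect-bored), spotted, sprouted,
and broken, alongside the undamaged *perfect* class. In pooled samples the
kernels touch and partially cover one another ("adhesion"), which defeats
classical watershed/concavity splitting and per-class semantic
segmentation alike: what is needed is a per-object pixel mask, i.e.
instance segmentation.

`grainseg` implements a Mask R-CNN-style two-stage instance segmenter
specialized for this regime, together with a synthetic kernel-scene
generator (so every stage is buildable and testable at desk scale without
a labeled grain dataset) and COCO-style evaluation. The whole network
stack — a reverse-mode autodiff engine, convolutional layers, SGD — is
implemented on numpy inside the package (`grainseg.nn`).

## The model

Three modifications to the standard detector target dense adherent grains:

1. **Channel attention on the backbone** (`grainseg.attention`). Each of
   the four residual stage outputs C2–C5 is gated by Efficient Channel
   Attention: global average pooling followed by a shared 1-D convolution
   across channels whose kernel size adapts to the channel count,
   k = nearest odd integer to |log₂C/γ + b/γ| (γ=2, b=1), then a logistic
   gate in (0,1). SE and CBAM blocks are provided for ablation.
2. **Bottom-up pyramid fusion** (`grainseg.pyramid`). On top of the
   top-down FPN levels P2–P5, a fine-to-coarse path builds the prediction
   levels: N2 = P2 and N(k+1) = conv3×3(pool(N(k)) + P(k+1)), shortening
   the route of localization-rich shallow features to three fusion steps.
   The classic 3×3 smoothing of the P-levels is removed when this path is
   used. A recursive-FPN variant is included for ablation.
3. **Re-tuned region proposals** (`grainseg.rpn`). Six anchor scales
   {8, 16, 32, 64, 128, 256} at aspect ratios {0.5, 1, 2} distributed over
   the pyramid levels; foreground/background screening at IoU 0.7/0.3 with
   the in-between band discarded; proposal NMS at 0.5 so that two adherent
   kernels are not merged into a single proposal.

Evaluation (`grainseg.metrics`) follows the standard definitions:
recall = TP/(TP+FN), precision = TP/(TP+FP), IoU(E,F) = |E∩F|/|E∪F|,
AP = area under the precision–recall curve (all-point interpolation),
mAP/mIoU = unweighted class means, at mask IoU threshold 0.5.

The synthetic generator (`grainseg.synthetic`) renders rotated-ellipse
kernels with class-specific damage motifs, resolves occlusion by z-order
(only *visible* pixels are annotated — a fully covered kernel gets no
annotation), applies the five standard augmentations (reduce brightness,
Gaussian noise, random salt points, translate, flip), and produces a
stratified 8:1:1 train/val/test split: the default recipe of 5 single-class
bases per category plus 100 mixture bases × 6 versions gives 780 images
split 624/78/78 with 480 mixture images in train.

## Worked example

```bash
python examples/05_metrics.py
```

prints

```
precision(TP=86, FP=14) = 0.86
recall(TP=91, FN=9)     = 0.91
AP of the two-detection example = 0.5
mean of six per-class APs = 0.8617 (rounds to 0.86)
```

— the closed-form metric definitions on worked instances: 86 correct among
100 positive predictions gives precision 0.86; the two-detection example
(a true positive at score 0.9, a false positive at 0.8, two ground truths)
has precision–recall points (1.0, 0.5) and (0.5, 0.5), enclosing area 0.5;
and the six-class mean shows mAP is the unweighted class average.

Training at desk scale:

```bash
python examples/06_train_tiny_detector.py   # 60-iteration smoke run
grainseg generate --n-single 5 --n-mixture 100 --seed 0 --out data/
grainseg train --variant am_fpn --iterations 300 --seed 1 --out runs/am_fpn
grainseg eval --checkpoint runs/am_fpn/checkpoint.npz --out runs/am_fpn/eval
grainseg ablate --iterations 300 --seed 1 --out runs/ablation
```

The four named variants are `baseline` (plain FPN), `am` (+ECA), `fpn`
(+bottom-up fusion), and `am_fpn` (both); `ablate` additionally runs the
six {SE, ECA, CBAM} × {recursive, bottom-up} fusion combinations.

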