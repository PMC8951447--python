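# Methods

## Overview

`irisynth` implements a self-supervised loop for iris segmentation:

1. **Mask sampling** — draw an 11-parameter eye configuration and
   rasterize its iris annulus and periocular (eyelid-aperture) ellipse.
2. **Conditional synthesis** — a U-Net generator, trained adversarially
   against a patch discriminator with a strong L1 term, maps the
   2-channel mask pair to a grayscale eye image.
3. **Self-supervised segmentation** — synthesized images inherit their
   conditioning masks as exact labels; a second U-Net (1-channel input,
   per-pixel softmax) is trained on them with cross-entropy summed over
   pixels.
4. **Evaluation** — PA/mPA/mIoU/FWIoU from a pooled pixel confusion
   matrix, and the Fréchet distance between Gaussian fits to embedded
   image sets.

A procedural renderer fabricates "real" eye images from the same mask
parameters so the loop needs no capture data.

## Mask model

Coordinates are 0-based, x = column, y = row, origin top-left; angles
in degrees counter-clockwise from +x. A pixel is foreground iff its
center satisfies the defining inequality — hard labels, no
anti-aliasing, because the masks feed a discriminator and a loss that
expect binary conditions.

The iris mask is the *annulus* (iris disc minus pupil disc): this is
the region carrying iris texture, which is what a segmentor must find.
An option intersects the annulus with the periocular ellipse to model
eyelid occlusion; it is off by default so the annulus area has a closed
form for verification.

Sampling order matters: `iris_r`, `x_ratio`, `y_ratio` are drawn first
because the offset intervals `[-ratio·iris_r/2, +ratio·iris_r/2]`
depend on them. Iris centers are drawn from the central 60% of the
frame (the full frame would put most shapes half out of view); the
pupil center is the iris center plus isotropic Gaussian jitter (sd
3 px), rejection-sampled until the pupil disc lies inside the iris
disc. Default intervals: PupilR [20, 60], IrisR [70, 120], xRatio
[1.3, 2.5], yRatio [0.4, 1.1], Degree [−15°, 15°].

## Synthesis network

* Generator: depth-8 U-Net at the nominal 256×256 resolution (4×4
  kernels, stride 2, instance norm, LeakyReLU 0.2 encoder / ReLU
  decoder, skip connections at every level, sigmoid output, dropout
  0.5 on the first five decoder stages). The innermost encoder and
  decoder stages skip normalization: the bottleneck map is 1×1, where
  instance statistics are undefined.
* Discriminator: five 4×4 stride-2 convolutions over the 3-channel
  (masks + image) stack, instance norm on the middle layers, sigmoid
  patch output. For a 256×256 input the feature maps after the fourth
  layer are 16×16 and the patch map is 8×8; the adversarial loss
  averages over patches.
* Losses: conditional adversarial objective with clamped logs
  (ε = 1e−7) plus λ·L1, λ = 100. The L1 term is the **per-pixel mean**
  absolute deviation, keeping λ's meaning independent of resolution.
  The generator's adversarial term uses the non-saturating form
  (maximize log D(x, G(x))) by default, with the minimax form behind a
  switch.
* Optimization: Adam (β₁ = 0.5, β₂ = 0.99), learning rate 1e−4, batch
  64, Gaussian N(0, 0.02) weight init — the full-scale recipe. One
  discriminator update and one generator update per iteration; the
  generator step is taken against the already-updated discriminator.
* Two optional stabilizers for short runs: `disc_lr_factor` trains the
  critic at a fraction of the generator's rate (with λ = 100 the L1
  term carries most of the learning signal, and a too-confident early
  critic mostly injects noise), and `ema_decay` synthesizes from an
  exponential moving average of the generator weights rather than the
  last iterate, smoothing late-iteration optimization noise.

The networks run on a compact numpy layer library with explicit
backward passes (im2col convolutions, scatter-add transposed
convolutions, instance-norm backprop, inverted dropout) and a handmade
Adam. Gradients are verified against numerical differentiation and
exact directional derivatives in the test suite. Everything is float32;
training is deterministic for a fixed seed in a single-threaded BLAS.

## Segmentation network

The generator architecture with a 1-channel input and an n-class
channel-softmax head (binary iris/background by default; a 3-class
background/periocular/iris mode is available). The loss is
cross-entropy **summed** over pixel positions — dividing by w·h
recovers the familiar mean form, which the tests assert numerically.
"Mini-batch SGD with Adam" is read as mini-batch stochastic training
using the Adam update rule. Full-scale recipe: lr 1e−5, batch 64, 10
epochs. Argmax ties break toward the lower class index.

## Renderer

The toy renderer composes, per mask configuration: skin background,
sclera inside the periocular ellipse, a textured iris annulus (radial
sinusoid + seeded smoothed noise, mimicking striations), a dark pupil,
optional additive Gaussian sensor noise, and an optional eyeglasses
mode (two specular glare discs and a frame arc). Default intensities
(pupil 0.05, iris 0.45 ± 0.18 texture, skin 0.75, sclera 0.95) keep the
iris band separable, so band-thresholding recovers the iris mask
almost exactly at zero noise — the alignment oracle for the pipeline.

What it does **not** emulate: real iris texture statistics, eyelashes,
off-axis gaze, blur, shadows, or sensor characteristics. Passing tests
therefore demonstrate that the machinery (sampling → synthesis →
self-supervised training → evaluation) works end to end and that
synthesized data carries usable label information — not that the
synthesis reaches capture-data realism.

## Desk-scale presets

The default `ExperimentConfig` exercises the full loop on one CPU:
64×64 working frames (mask sampling ranges rescaled proportionally),
200 rendered real-proxy pairs, 200 adversarial update pairs, 200
synthesized images, a 10-epoch segmentor, and a 64-image held-out test
set. At this scale the networks are narrowed (generator/critic base
width 24, segmentor 32, depth 6 so the bottleneck is 1×1 at 64×64) and
the learning rates raised to 2e−3 — with only a few hundred Adam steps,
the full-scale 1e−4/1e−5 rates would barely move the weights. The
desk preset also enables the two stabilizers (disc_lr_factor 0.25, EMA
0.97) and disables segmentor dropout, which at this width/epoch budget
only adds variance. The three-seed trend configuration shrinks further
(32×32, depth 5, 96 + 96 images, 120 update pairs, 8 epochs) since it
compares two training-set compositions rather than chasing a quality
ceiling.

## Numerical choices

* Logs clamped at 1e−7 (adversarial) / 1e−12 (segmentation loss).
* FID matrix square root via eigendecomposition of the symmetrized
  product Σ_r^{1/2} Σ_g Σ_r^{1/2}; eigenvalues clipped at 0, result
  clipped at 0. Covariances must be symmetric PSD within 1e−6.
* mPA/mIoU exclude classes with zero ground-truth pixels from the
  class average (0/0 ratios); FWIoU is unaffected (zero weight).
* Mask resizing is nearest-neighbor with re-binarization; images are
  bilinear. Augmentation applies one logged crop/flip/resize to image
  and masks alike, and replaying the log is bit-exact.
* Degenerate inputs raise: empty datasets, non-divisible resolutions,
  scores outside [0, 1], crops larger than the source, sampling ranges
  that admit no valid configuration.

## Known limitations

* The renderer's four-level appearance makes segmentation far easier
  than on capture data; desk-scale metric values are not comparable to
  real-dataset numbers.
* Instance norm has no running statistics, so eval-mode behaviour
  equals train-mode normalization (per-sample), as in the Pix2Pix
  lineage.
* The numpy core is single-process and unbatched across devices; it is
  sized for 32–256 px experiments, not production training.
* The bundled FID embedder (downsampled pixels + moments) is
  deterministic and dependency-free but not comparable to
  inception-based scores; treat its values as relative only.
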