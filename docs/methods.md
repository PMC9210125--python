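# Methods

## Problem and model

Single-image super-resolution (SR) recovers a high-resolution (HR)
grayscale image Y from a low-resolution (LR) observation X obtained by
bicubic downscaling at an integer factor r ∈ {2, 4, 8}. The package
implements a GAN-based SR network for grayscale medical-style images:

- **Generator G.** The LR input is first bicubically upsampled to the HR
  size and passed through a stem of bottleneck residual units (1×1 → 3×3 →
  1×1, expansion 4, internal width 64 by default) followed by a 3×3
  convolution down to 32 channels. The trunk then maintains four parallel
  streams at full, 1/2, 1/4 and 1/8 resolution with channel widths
  (32, 64, 128, 256): each of stages 2–4 appends one lower stream through a
  stride-2 3×3 convolution and runs 1, 4 and 3 exchange modules
  respectively. An exchange module applies 4 basic residual blocks (two 3×3
  convolutions each) per stream and then a cross-resolution fusion in which
  every stream receives every other stream — downward paths chain stride-2
  3×3 convolutions, upward paths use bilinear interpolation plus a 1×1
  convolution, and ReLU is applied to the converted sum. Aggregation lifts
  the three lower streams back to full resolution with **transposed
  convolutions** of (kernel, stride) = (5, 2), (7, 4), (11, 8) rather than
  bilinear interpolation, concatenates all four maps (480 channels) and
  predicts the residual-free output with a single 1×1 convolution. All
  convolutions are followed by ReLU except fusion branch tips and the
  prediction layer; the generator has no batch normalisation.
- **Discriminator D.** Eight 3×3 convolutions with channels
  64, 64, 128, 128, 256, 256, 512, 512 and strides 1, 2, 1, 2, 1, 2, 1, 2
  (no pooling anywhere), batch normalisation after layers 2–8, ReLU
  activations, then two dense layers (1024 → 1) and a sigmoid giving the
  probability that the input is a real HR image.

Training minimises, in alternation,

- discriminator: −E[log D(Y)] − E[log(1 − D(G(X)))],
- generator: L_total = a1·L_MSE + a2·L_adv, with L_MSE the pixelwise mean
  squared error over the r·W × r·H output and L_adv the batch mean of
  −log D(G(X)).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| scale r | 4 | LR→HR linear factor; {2, 4, 8} supported |
| widths | (32, 64, 128, 256) | stream channel counts; must double per level |
| a1, a2 | 1.0, 0.001 | content / adversarial loss weights |
| initial_lr | 1e-4 | Adam step size, halved every 50 epochs |
| total_epochs | 200 | full-scale schedule length |
| batch_size, hr_patch | 16, 96 px | minibatch geometry; LR patches are hr_patch/r |

a1/a2 follow the SRGAN convention (the network family this discriminator
and loss follow); both are exposed in the configuration. The learning-rate
schedule `initial_lr / 2^floor(epoch/50)` over 200 epochs is the published
recipe; desk-scale experiments in `medsrnet.experiments` instead use a flat
Adam rate of 1e-3, the standard Adam default, because a few hundred steps
at 1e-4 barely move a freshly initialised network.

## Numerical and design choices

- **Intensity convention.** Images live in [0, 1] (peak 1 for PSNR);
  files are 8/16-bit PNG/TIFF scaled by the code-value maximum. Writing
  rounds half away from zero, so a write/read round trip is exact to one
  code step.
- **Bicubic operator.** Keys kernel with a = −0.5, pixel-centre
  (align-corners-false) grid, kernel support widened by the scale factor on
  downscale (antialiasing). This is pinned so the degradation operator,
  the bicubic baseline and the pre-upsampling step are identical and
  reproducible; tests cross-check it against an independent resampler.
- **Pre-upsampled input.** The generator's top stream lives at HR size:
  the LR input is bicubically upsampled ×r before the stem. The internal
  drops of ×2/×4/×8 are then exactly undone by the (5,2)/(7,4)/(11,8)
  transposed convolutions, whose padding/output-padding are solved in
  closed form (`deconv_geometry`): out = (in−1)s − 2p + k + op = in·s.
- **Initialisation.** He fan-in initialisation from a run seed. The
  closing convolution of every residual unit and every fusion branch tip is
  additionally scaled by 0.1 at initialisation (the EDSR/ESRGAN residual
  scaling); without it the variance of the activations roughly doubles at
  every residual addition and fusion sum — the generator has no batch
  normalisation to absorb this — and the initial output explodes to ~1e8.
- **Sigmoid clamp.** Discriminator probabilities are clamped to
  [1e-7, 1 − 1e-7] before any logarithm; clamp hits are counted and
  reported on the training log rather than silently ignored.
- **Adversarial sum.** The adversarial term is the batch *mean* of
  −log D(G(X)) so its magnitude is batch-invariant.
- **Infinite PSNR.** Exact pairs report +inf and are excluded from dataset
  means with a logged count.
- **Fusion order.** Each exchange module fuses at its end; whether the
  single stage-2 module precedes or follows its fusion is not constrained
  by the architecture family, and end-of-module fusion is used uniformly.
- **Prediction head.** The 1×1 prediction convolution maps the 480
  concatenated channels directly to 1 output channel, with no activation;
  outputs are clipped to [0, 1] only at inference.

## Autograd core

No deep-learning framework is used: `medsrnet.nn` is a compact tape-based
reverse-mode autodiff engine on numpy arrays with the layers this model
needs (conv2d and conv_transpose2d via im2col/col2im with BLAS matmuls,
bilinear upsampling as separable interpolation matrices, batch
normalisation, dense layers, Adam). Gradients of every structured op are
verified against central finite differences in float64; training runs in
float32. Inference uses a no-grad mode that skips graph construction.

## Synthetic phantoms

Phantoms composite nested soft ellipses, small bright/dark lesion discs
and a low-amplitude sinusoidal texture on a uniform background, clipped to
[0, 1]; an optional Gaussian blur produces smooth low-frequency variants.
They emulate only the image *features* SR must recover — sharp boundaries,
compact blobs, mild texture — not CT acquisition physics (no beam
hardening, noise correlation, windowing or anatomy). Passing tests
therefore demonstrate that the pipeline is correct and trainable, not that
clinical-grade SR quality is achieved on real scans.

## Desk-scale experiments and problem sizes

The reference experiments (`medsrnet.experiments`) are sized for a single
CPU core:

- **Overfit-one-image**: widths (8, 16, 32, 64), one 128×128 phantom,
  scale 4, pure-MSE, full-image batches, 500 Adam steps at 1e-3, keeping
  the best-so-far model (PSNR on the fitted image checked every 25 steps)
  just as the full training loop keeps its best-validation checkpoint —
  Adam at a flat rate occasionally produces one-step loss spikes, and the
  converged model, not an endpoint sample, is what the comparison is
  about. The trained model's PSNR exceeds the bicubic baseline by well
  over the 0.5 dB margin asserted in the acceptance test (typically
  +1.5 to +3 dB depending on the seed).
- **Ablation**: bilinear vs deconvolution aggregation heads under
  identical seeds, 20 steps on a 64×64 phantom; the deconvolution head has
  strictly more parameters, by construction of the transposed-convolution
  kernels.
- **Discriminator separability**: a tiny-channel discriminator separates
  bright from dark 32×32 toy images within 200 steps.

These sizes are deliberate down-scalings: full-scale training (700
clinical images, 200 epochs, GPU) is out of scope, and no attempt is made
to reproduce published benchmark PSNR/SSIM tables.

## Known limitations

- CPU-only numpy training is orders of magnitude slower than a GPU
  framework; the defaults are desk-scale.
- Only integer scales {2, 4, 8} and square-pixel grayscale inputs are
  supported; no blind/real-world degradation modelling.
- The discriminator evaluates fixed-size patches (dense layers are bound
  to the build-time input side).
- GAN training at tiny scale is demonstrative; no perceptual (VGG) loss
  or stabilisation tricks beyond optional gradient clipping are provided.
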