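# Methods

This note records the models, algorithms, and design choices behind
`watunet`, in the order data flows through the package.

## Synthetic speckle phantoms (`watunet.phantom`)

Real breast-ultrasound data cannot ship with the package, so all testing
and the reproduction script run on synthetic phantoms designed to carry
the features the segmentation task depends on, and nothing more.

**Speckle model.** B-mode speckle is multiplicative: the generator draws
two independent Gaussian fields, smooths each with a Gaussian kernel
(`speckle_smoothing`, default 1.5 px), and uses the sum of their squares
— the squared envelope of a complex Gaussian field, i.e. a
Rayleigh-amplitude analogue — normalised to unit mean as a
multiplicative texture on a mid-gray background (level 115). This
reproduces the granular, exponential-intensity look of log-free B-mode
texture without simulating wave physics.

**Lesions.** Lesions are hypoechoic: pixel intensities inside the mask
are scaled by `lesion_contrast` (default 0.45), with a one-pixel
Gaussian softening of the boundary. Class geometry:

- *benign* — one ellipse with axis ratio drawn in [0.55, 0.95] and
  random orientation;
- *malignant* — a star-convex region whose radius profile is perturbed
  by random angular harmonics of orders 3–8 (amplitudes ≤ 0.05 each)
  plus 2–5 Gaussian spicule bumps (width 0.15–0.30 rad, amplitude
  0.10–0.30 of the base radius), clipped to [0.4, 1.8]·r₀ so the region
  stays simply connected;
- *no_mass* — empty mask.

The target area fraction is drawn from `lesion_area_range` (default
3–15 % of the frame); for malignant shapes one fixed-point rescale of
the radius profile corrects the discretisation error. A sample is
redrawn (up to 30 times) until the pixel-counted fraction lands inside
the range and the mask is a single 4-connected component; a
configuration for which this cannot succeed raises a diagnostic.

**Class mix.** Default proportions follow the clinical sweep dataset the
tool targets: 2048 : 820 : 950 (no mass : benign : malignant) out of
3818 frames. Counts are apportioned by largest remainder, so the total
is exact and deterministic.

**What the phantoms do not model:** acoustic shadowing and enhancement,
depth-dependent attenuation and focus, probe-sector geometry,
multi-lesion frames, and real lesion texture heterogeneity. Passing the
phantom suite therefore demonstrates that the architecture, training
loop, and statistics are implemented correctly and can learn
hypoechoic-region segmentation — not that the printed clinical metrics
transfer to patient data.

## Preprocessing (`watunet.preprocess`)

**CLAHE** runs on the 8-bit image at native resolution (tile statistics
are better defined before resampling), via scikit-image. The clip limit
uses the 8-bit convention — a multiple of the uniform histogram level,
default 2.0 with an 8×8 tile grid — and is divided by 256 to obtain the
normalised fraction scikit-image expects. A perfectly flat image stays
flat (up to the global rescale of the equalised output).

**Resizing** is bilinear with anti-aliasing for images (then scaled to
[0,1]) and nearest-neighbour for masks, which therefore remain strictly
binary.

**Augmentation** composes rotation (±15°), zoom ([0.9, 1.1]),
horizontal flip, width/height shifts (±10 %), and shear (±0.1 rad)
about the pixel-grid centre into one affine transform applied
identically to image (bilinear) and mask (nearest, re-binarized at 0.5);
brightness ([0.8, 1.2]) multiplies the image only. Out-of-frame pixels
are filled with black, matching the dark sector background of ultrasound
frames. Magnitudes are deliberately conservative — aggressive zoom or
brightness distortion destroys diagnostically relevant detail in
ultrasound — and all are configurable. `balance_classes` tops up each
class to a common target count with fresh augmentation draws, which is
how class-imbalance bias is mitigated during training.

## Gates (`watunet.gates`)

**Additive attention gate.** Skip features x and gating signal g are
projected by 1×1 convolutions W_x and W_g to a common width (equal to
the channel count of x), summed, passed through swish (σ₁), projected to
one channel by W_s, and squashed by a sigmoid (σ₂):

    a = σ₂( W_s · σ₁( W_x·x + W_g·g ) ),   x_out = x ⊙ a

The coefficients a lie strictly in (0,1) and broadcast over channels, so
|x_out| ≤ |x| elementwise. Both biases are fixed at zero (they add
nothing empirically and keep the gate linear in its inputs before the
nonlinearities).

**Wavelet gate.** Each channel of x undergoes a single-level 2-D
Daubechies-2 DWT in periodization mode. Periodization is the one
extension mode for which every sub-band is exactly half the input
resolution, which keeps the shape bookkeeping of a UNet clean; the
filters are orthonormal, so the transform conserves energy and inverts
exactly. The transform is implemented as two fixed matrix products (rows
and columns) built from the db2 analysis filters with circular wrapping;
it matches PyWavelets' `dwt2(mode="periodization")` to 1e-10 and its
transpose is its inverse, which is also how the gradient flows through
it during training.

Sub-band routing: the approximation band LL — the denoised, contextual
component — is attention-gated against a coarse decoder feature; the
horizontal and vertical detail bands LH and HL pass through unchanged;
the diagonal band HH, dominated by speckle noise, is discarded (a
`keep_hh` flag retains it for ablation). The three streams are
concatenated (3C channels) and upsampled ×2.

**Resolution reconciliation.** The DWT halves the skip resolution while
the decoder concatenates at full resolution. The gate therefore runs at
sub-band resolution — where the coarser decoder feature natively lives,
entering the attention gate through its own 1×1 projection — and the
concatenated bands are upsampled afterwards by a learned 3×3 stride-2
transposed convolution. The alternative (interpolating sub-bands up
front) would smear the band structure before the gate sees it. The
functional API defaults to nearest-neighbour upsampling so the gate math
is testable without trained weights.

## Network (`watunet.network`)

One UNet backbone serves four model variants that differ only in the
skip tensor:

| mode | skip tensor | channels |
|---|---|---|
| `plain` | encoder feature | C |
| `attention` | attention gate over the encoder feature, gated by the decoder's upsampled feature | C |
| `sharpen` | fixed per-channel 3×3 Laplacian-sharpening kernel (sums to 1; replicate borders) | C |
| `watunet` | wavelet gate ∥ attention gate, concatenated | 4C |

The backbone: `depth` (default 4) encoder blocks of two 3×3 stride-1
convolutions each followed by batch norm and swish, 2×2 max-pooling,
and dropout (rate 0.1); a bottleneck block with the same structure and
encoder-side dropout; a decoder of 3×3 stride-2 transposed
convolutions, skip concatenation, a conv block, and dropout (rate 0.5);
a 1×1 convolution and sigmoid produce the probability map. Channel
width doubles per level from `base_channels`. The parallel (rather than
sequential) arrangement of the two gate streams in `watunet` mode lets
the frequency-selective and saliency-selective pathways contribute
independent information to the decoder.

The network runs on a small tape-based numpy autodiff engine written
for this package (`watunet.autograd`): tensors are NHWC float32, and
convolutions are evaluated as nine shifted matrix products, which is
what makes CPU training of the full architecture practical. Every
operation's gradient is verified against central finite differences in
the test suite. Initialisation is He-uniform from a seeded generator;
two builds with the same seed are bitwise identical.

## Objective and metrics (`watunet.objectives`)

Training minimises mean pixelwise binary cross-entropy plus soft Dice
loss (unweighted 1:1 sum; weights configurable). The soft Dice term uses
a smoothing constant of 1e-6 so empty masks — common, since half the
frames have no mass — do not produce 0/0. The loss gradient is computed
in closed form and fed to the network's backward pass.

Evaluation binarizes at 0.4 with a strict inequality (the ROC
convention) and reports accuracy, precision, sensitivity, specificity,
F1, and Dice from pooled pixel counts over the evaluated set
(micro-average), matching the pixel-level framing of the statistical
comparison; per-image records are also emitted. Ratios with zero
denominators are reported as missing (`None`), never silently as zero.
On binary masks Dice and F1 are the same number, which the tests assert.

## Model comparison (`watunet.stats_compare`)

Per model pair, per-pixel correctness against ground truth is pooled
over all test images into one 2×2 paired table; the discordant counts b
and c give McNemar's statistic (b−c)²/(b+c), referred to chi-squared
with 1 df. No continuity correction is applied by default (pixel counts
are enormous; a flag provides it). With b+c = 0 the test is undefined
and p = 1 is reported with a flag.

The C(k,2) p-values enter the standard Benjamini–Hochberg step-up
procedure: sorted ascending, rank i gets critical value (i/m)·α, and
every pair ranked at or below the largest i with p₍ᵢ₎ ≤ (i/m)·α is
significant. The published comparison table this reproduces lists ranks
that do not follow ascending p-value order; the implementation follows
the textbook ordering, which is the procedure's definition.

## Training protocol and scale (`watunet.pipeline`)

Optimisation uses Adam with learning rate 0.001, β₁ = 0.9, β₂ = 0.9,
ε = 1e-7, shuffled batches, and best-model selection by the highest
validation Dice across epochs. Splits are 80:10:10 with floor
arithmetic (validation and test get ⌊0.1·n⌋ each, remainder to
training) — 3818 frames give 3056/381/381 — stratified by class by
default. One master seed fans out to phantom, split, augmentation, and
per-model initialisation/shuffling sub-seeds through
`numpy.random.SeedSequence`, so an entire comparison study is
reproducible bit for bit.

The reference protocol (300 epochs, 128×128, batch 32, base width 64)
is GPU-scale. The package's **desk-scale preset** — used by the test
suite and the reproduction script — keeps the full architecture but
shrinks the problem: 200 phantoms at 64×64, `base_channels` 8, depth 4,
15 epochs, batch size 8 (smaller batches give more optimisation steps
per epoch, which converges faster in this regime). On one CPU core a
two-model study completes in a few minutes. Under these
conditions both the plain and the gated model exceed 0.6 validation
Dice within the epoch budget, and the gated model converges markedly
faster in the first epochs. A caution on comparing variants at this
scale: with a 20-image test set, the seed-to-seed spread of test Dice
(≈0.04–0.05 across replicates) is as large as typical between-model
gaps, and the high-contrast phantom lesions leave a plain UNet little
room to be beaten. Desk-scale replicates therefore do not reliably
reproduce the ranking a full-scale clinical comparison reports;
resolving such rankings needs the larger test sets the statistical
machinery in `stats_compare` is designed for.

## Known limitations

- The phantoms omit the acoustic artefacts listed above; clinical
  performance claims are out of scope for this codebase.
- Training is float32 on CPU; at much larger widths or resolutions the
  numpy engine is the bottleneck.
- The CLAHE clip-limit mapping between the 8-bit and normalised
  conventions is approximate across tile sizes.
- Batch-norm statistics at batch size 8 are noisy; the desk-scale runs
  accept this in exchange for more update steps.
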