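# Methods

This note records the modelling assumptions, default parameters, and design
choices behind `vesselseg`, and what the synthetic phantoms do and do not
establish about real fundus data.

## Preprocessing

The enhancement pipeline assumes an RGB fundus photograph in which vessels
are darkest and best separated from the background in the green channel.
Three derived channels — green, CLAHE(green), green^γ — are stacked and
converted to grayscale.

Defaults and rationale:

- **CLAHE**: clip limit 2.0 (absolute convention; mapped internally to
  scikit-image's normalized limit), 8×8 tile grid. Common settings for
  ~565×584 fundus frames; both configurable. A constant image is returned
  unchanged (there is no contrast to redistribute).
- **Gamma**: 1.2, applied as a forward power transform on the [0, 1] green
  channel. The step is genuinely ambiguous — "removing" a gamma correction
  can be read as applying γ < 1 or γ > 1 — so the exponent is a single
  signed knob; γ = 1/1.2 gives the inverse reading. With dark-on-bright
  vessels, γ > 1 deepens vessel-background separation in the mid-tones.
- **Grayscale weights**: equal (1/3 each). The stacked channels are not
  R/G/B semantically, so luminance weights have no justification here;
  they remain configurable.
- All computation is floating point; quantization happens only at file
  export.

## Network architecture

The BFCN is a U-shaped encoder–decoder. Choices the architecture
description leaves open, and how they were fixed:

- **Dilation rates** {1, 2, 4, 8}: effective kernels 3, 5, 9, 17 px,
  spanning the 1–8 px vessel-width range with margin; configurable as any
  4 pairwise-distinct rates.
- **Depth / widths**: default depth 4 with channels (32, 64, 128, 256) and
  2×2 max-pool downsampling — standard U-shaped sizing for 128×128
  patches. The desk-scale configuration used throughout the tests is
  depth 3 with base 8.
- **MSIE fusion**: the five branch outputs (each at the block's output
  width) are concatenated and fused by a 1×1 convolution, preserving
  per-scale information until after fusion; summation would mix scales
  before the recalibration gate can weigh them.
- **Recalibration bottleneck**: two 1×1 layers with reduction ratio 4 and
  an intermediate ReLU (squeeze-and-excite convention).
- **Transfer layer**: the five 1×1 convolutions are allocated 2 + 2 + 1 —
  two on the spatially pooled descriptors (stage 1, channel gate α), two
  on the channel-pooled maps (stage 2, spatial gate β), one output
  projection. This is the only allocation consistent with two sigmoids,
  two pooling stages and two channel-processing stages.
- **Gate mode**: `combined` (default) outputs β ⊙ (α ⊙ X): both gates act
  on the skip. `literal` outputs β ⊙ X, the narrower reading in which α
  only shapes β. Both are implemented; all end-to-end results use
  `combined`.
- **Side inputs**: the enhanced input is average-pooled by 2^level, lifted
  by a 3×3 convolution (half the base width), and concatenated with that
  level's features — the simplest image-pyramid fusion; addition would
  force the lift to match the full feature width.
- **Decoder upsampling**: 2×2-kernel, stride-2 transposed convolution —
  exact ×2 with no overlap artifacts and a simple exact gradient.
- **Initialization**: He fan-in scaling, biases zero, seed recorded in
  `ModelConfig`.

## Numerical core

The network runs on a small reverse-mode autodiff layer over float64 NumPy
arrays (`nn.py`), with convolutions lowered to im2col + BLAS matmul.
Conventions that matter for reproducibility:

- ReLU uses the standard subgradient relu′(0) = 0. Finite-difference
  probes straddling the kink will disagree there; the gradient tests
  therefore keep pre-activations off exact zero.
- Max-pool and channel-max split gradients equally among tied maxima
  (deterministic and symmetric).
- Cross-entropy clips predictions to [10⁻⁷, 1 − 10⁻⁷] before the
  logarithm; the loss is summed over pixels and averaged over the batch,
  which keeps lr = 10⁻³ stable across patch sizes.
- Forward passes, training runs and phantom generation are bit-reproducible
  given fixed seeds (single-threaded BLAS assumed for exactness).

## Training

Adam with lr 10⁻³, β₁ 0.9, β₂ 0.999, ε 10⁻⁸; batch 16; plateau decay
multiplies lr by 0.1 after 10 epochs without relative improvement > 10⁻⁴
of the monitored quantity. The monitor is the training loss: no validation
split is part of the reference recipe, so the optional held-out fraction
(`val_fraction`, default 0) exists only as a diagnostic. Divergence
(non-finite loss) aborts with an error rather than continuing silently.

## Patching

Training patches are sampled uniformly over windows fully inside the
image; with a FOV mask, candidate windows must be ≥ 50 % inside the field
of view (summed-area table), avoiding all-black border patches. Test-time
windows slide row-major at stride 5 (default), zero-filling overhang;
overlapping predictions are recomposed by per-pixel arithmetic mean —
unbiased and standard for dense overlapping inference; the alternative
(overwrite) would make the result depend on window order.

## Postprocessing

Two sharpening modes: `laplacian_subtract` (G = F − ∇²F with the
4-neighbour Laplacian) and the default `abs_template`, which convolves the
probability map with the |·|/10 transform of the 8-neighbourhood Laplacian
stencil (centre 0.8, neighbours 0.1, kernel sum 1.6). The default is the
mode applied to probability maps in the method this package implements;
it resets each pixel to a neighbourhood aggregate, which is what bridges
1–2 px gaps at small-vessel endings. Borders use replicate padding
(probability maps have no meaningful exterior), and outputs are clipped to
[0, 1] so thresholding stays well-defined. Sharpening operates on the
reassembled full-size map, not on individual patches, so window seams
cannot create artificial edges. Thresholds are per-dataset configuration
(0.5 for phantoms).

## Evaluation

Metrics are pooled pixel counts inside the FOV (configurable to
whole-frame, or per-image by summing `ConfusionCounts` yourself). A metric
with a zero denominator is NaN, never a silent 0, and all-zero counts
raise. AUC integrates the ROC trapezoidally over all unique score
thresholds; ties are handled exactly (the result equals the Mann–Whitney
statistic, which the tests verify).

## Synthetic phantoms

The generator emulates the properties the pipeline is sensitive to:
a circular FOV disc; branching vessel trees grown inward from the disc
boundary by biased random walks with a weak centripetal pull; widths
drawn from 1–8 px tapering toward the periphery; a truncated-Gaussian
cross-profile whose support *is* the ground-truth mask (so truth and image
are pixel-aligned by construction); strongest vessel contrast in the green
channel; a linear illumination ramp; additive Gaussian noise. With
`break_rate > 0`, short runs of segments are left out of the rendering but
kept in the truth and recorded in a break mask — the test bed for the
sharpening-continuity property.

Defaults, chosen once for realism of the low-contrast regime: 256×256
frames, 6 trees, vessel/background contrast 0.35, illumination amplitude
0.15, noise σ 0.05, break rate 0. Under these settings the vessel fraction
inside the FOV falls in 0.05–0.20 across seeds (checked over 20 seeds),
bracketing the ~0.09–0.13 vessel density of expert-annotated fundus
datasets.

What the phantoms do **not** model: optic disc, fovea, lesions and
exudates, texture and colour variation of the retina, camera vignetting
beyond a linear ramp, and inter-observer annotation ambiguity. Passing the
end-to-end tests therefore shows that the implementation learns and
recovers thin low-contrast tubular structure under noise and uneven
illumination — not that it reaches benchmark accuracy on real datasets,
which requires the real images and full-scale training.

## Problem sizes used by the test suite

The suite's one training run uses the desk-scale configuration: depth 3,
base 8, 200 patches of 64×64 from four phantoms, 20 epochs, batch 16
(~4 minutes on one CPU core), evaluated on a held-out phantom with a
64/32 sliding window. Unit and oracle tests run on ≤ 9×9 feature maps. The
full-scale defaults (depth 4, base 32, 128×128 patches, stride 5) are
exercised for shape and contract correctness, not trained in the suite.

## Known limitations

- CPU-only and float64: full-scale training (10⁴ patches × 200 epochs) is
  out of reach; the package targets correctness and desk-scale studies.
- No data augmentation, no test-time augmentation, no morphological
  cleanup — deliberately outside scope.
- `sample_training_patches` with a very restrictive FOV constraint falls
  back to unconstrained sampling after a bounded number of rejections.
- The probability-map PNG export quantizes to 16 bits; round-tripping
  through files loses ~1.5×10⁻⁵ of resolution.
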