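# Methods and design notes

## The logistic-type intensity family

The package's statistical core is the location–scale family

    f(y; μ, σ, p) = C(p) · (p + z²) · e^(−z) / (σ (1 + e^(−z))²),
    z = (y − μ)/σ,   C(p) = 3/(3p + π²),

i.e. the standard logistic density g(z) = e^(−z)/(1+e^(−z))² reweighted by
the even polynomial (p + z²). Because ∫ z² g(z) dz = π²/3, the normalizer is
exactly 1/(p + π²/3) = 3/(3p + π²); at the two-parameter setting p = 4 it is
3/(12 + π²). The density is symmetric about μ with variance

    Var(y) = σ² (p π² + 7π⁴/5) / (3p + π²)    (≈ 8.04 σ² at p = 4),

from ∫ z⁴ g = 7π⁴/15. All evaluations go through the log-density with
softplus terms, so the pdf is finite and correct for |z| up to the float
range; quadrature of the pdf over ±60σ agrees with 1 to ≈1e-15.

A note on parameter conventions: the two published component fits used as
default tissue anchors report "σ²" values of 94.2568 and 128.784 on an 8-bit
intensity scale. We read these as the *squared scale parameter* (σ = 9.71 and
11.35), not the distribution variance; under the variance reading the scales
would be ~3.4 and the two tissue modes would be implausibly narrow for CT.
Under our reading the two classes overlap substantially (distribution sd
≈ 27.5 and 32 against a 61-unit location gap), which matches the behavior of
real lung/tissue intensity histograms: the pooled histogram is near-unimodal
and per-pixel Bayes-optimal labeling is imperfect even at the true
parameters. Tests that need clean class separation construct it explicitly
rather than relying on these anchors.

There is no closed-form quantile, so sampling inverts a trapezoid-rule CDF
tabulated on a 4,096-point grid over μ ± 40σ (tail mass beyond the grid is
< 1e-14) with monotone linear interpolation. A KS check of 10,000 draws
against the numerical CDF passes comfortably.

## EM for the K-component mixture

Responsibilities are computed in log space (logsumexp), so mixtures remain
well-conditioned when a pixel sits far into every component's tail; if every
component underflows to zero density the fit aborts with the offending pixel
index rather than propagating NaNs.

The M-step weight update is the standard mean responsibility. For (μᵢ, σᵢ)
the weighted score equations of this family have no closed form — the
location score involves both the polynomial term and the logistic tilt — so
the default M-step maximizes each component's responsibility-weighted
log-likelihood numerically (Nelder–Mead over (μ, log σ), started at the
current iterate). Because the initial simplex contains the current point,
the update can only improve the weighted likelihood, which preserves the
generalized-EM ascent property; the observed-data log-likelihood is
asserted non-decreasing (slack 1e-9) in the tests and acceptance script.

An alternate `m_step="fixed_point"` mode performs one damped multiplicative
update of σ² derived from rearranging the σ score equation
Σ r (1 + z h′(z)) = 0 into σ² ← σ² · R with R = Σ r[2z s(z) − z −
2z²/(p+z²)] / Σ r (s the logistic sigmoid; R = 1 exactly at the stationary
point), with μ from a bounded 1-D solve. Any component whose fixed-point
step would lower the weighted likelihood falls back to the numerical MLE
update, so both modes are ascent-preserving.

Numerical guards: scales are floored at 1e-3; a component whose mean
responsibility falls below 1e-8 raises a collapse error naming the
component; constant input with K > 1 is rejected up front. Convergence is
declared when no parameter (weight, location, scale) moves by more than
`tol` (default 1e-3, the model's conventional estimation error); hitting
`max_iter` (default 500) returns a trace flagged `converged=False` rather
than raising — non-convergence is a result, not a failure.

Initialization places locations at the (i−0.5)/K quantiles (or 1-D k-means
centers) with equal weights 1/K, and sets each scale from the within-group
standard deviation divided by sd(z) = √8.04 so that the initial components
have roughly the right spread. Segment-count estimation smooths a 256-bin
histogram with a Gaussian kernel (default bandwidth: 1/64 of the intensity
range) and counts peaks whose prominence exceeds 5% of the tallest bin;
degenerate inputs return 1. The bandwidth matters: modes closer than a few
kernel widths merge, so K estimation is reliable only for class separations
of several scale units — which is why the segmentation pipeline lets K be
fixed per run.

Mixture component labels are arbitrary. When a binary ground-truth mask is
available the pipeline reports overlap metrics after choosing the label
subset that maximizes Dice (greedy union, adding the best-gaining label per
pass); PRI/VOI/GCE need no such alignment since they are label-permutation
invariant.

## Preprocessing chain

Stage order (window → CLAHE → Wiener → resize → normalize) is configurable;
the default mirrors the usual enhance-then-denoise CT display practice.

* **Hounsfield windowing** maps [center − width/2, center + width/2] linearly
  onto [0,1] and clamps outside. Presets: lung (center −600 HU, width
  1500 HU) and soft tissue (center 50 HU, width 400 HU), both overridable.
* **CLAHE** is implemented directly against its defining contract: per-tile
  histograms (default 8×8 tiles, 256 bins) are clipped at
  `clip_limit × tile pixel count` (default 0.01), the excess is spread
  uniformly over all bins in a single pass (so a bin can exceed the ceiling
  by at most excess/n_bins), and each pixel blends the equalization mappings
  of its four surrounding tile centers bilinearly (clamped at borders). With
  one tile and an unbounded clip limit this reduces *exactly* to global
  histogram equalization, which the tests verify against an independently
  coded reference. The in-package implementation (rather than an off-the-
  shelf one) keeps that reduction and the per-tile clip bound exactly
  checkable.
* **Wiener filtering** is the local adaptive estimator
  out = m + max(0, v − v_n)/max(v, v_n) · (x − m) with window means/variances
  (default 3×3) computed with reflective borders and the noise variance
  either fixed or estimated as the mean local variance. Interior pixels agree
  with `scipy.signal.wiener` exactly; borders differ only by the padding
  convention.
* **Resize** uses bilinear/area resampling (anti-aliased when downsampling);
  **normalize01** min-max rescales with the convention that constant images
  map to zeros. Both are deterministic and fix constant images.
* **Rotation augmentation** emits 8 copies at 45° steps; axis-aligned angles
  use exact grid rotation, diagonal angles resample (bilinear for images,
  nearest-neighbor for masks, reflective padding), the same transform applied
  to image and mask.

## The segmentation network

The network is built on a small in-package reverse-mode autodiff engine over
numpy (same-padding conv, 2×2 stride-2 transposed conv, 2×2 max-pool, ReLU,
sigmoid, concat, dropout, and the scalar ops a Dice loss needs). Every
primitive's backward pass is verified against central finite differences,
as is the end-to-end gradient of the full model. Float64 single-threaded
execution makes training bit-reproducible for a fixed seed.

Architecture: `depth` encoder levels of [conv 3×3 → ReLU] ×2 then max-pool,
dropout (rate 0.5) on the pooled bottom representation, and a mirrored
decoder of transposed-conv upsampling (followed by ReLU), skip concatenation
from the matching encoder level and two convolutions; filters double per
level from `base_filters` = 8. The head is a 1×1 convolution with sigmoid
(default) or a two-class softmax, which for one output channel is computed
as sigmoid of the logit difference. `skip_mode="nested"` instead builds the
densely re-aggregated grid of intermediate nodes X(i,j), each fed by all
previous same-level nodes plus an upsampled deeper node — the nested-skip
variant of the encoder–decoder family. Input sides must be divisible by
2^depth; at depth 5 a 128×128 input walks 128→64→32→16→8→4.

Where the design was genuinely open we chose: doubling filter schedules
(anchored by the 8-filter first layer); a symmetric decoder that returns to
input resolution so predictions can be scored against full-size masks;
dropout at the bottleneck only; ReLU after transposed convolutions; Dice
smoothing ε = 1 in numerator and denominator; L2 (λ = 0.001) applied to
convolution kernels only, added to their gradients as 2λw.

Training: Adam (lr 0.001, β = 0.9/0.999), batch size 32 (clamped to the
dataset), default 100 epochs, seeded shuffling, per-epoch train/val loss and
thresholded Dice computed in eval mode, best-validation checkpoint retained
(best-train when no validation fold exists). The dataset splitter shuffles
once with the configured seed and partitions 70/15/15 (train/val floor,
remainder to test).

## Synthetic phantoms

`generate_mixture_image` draws every pixel from the mixture component of its
region label — exactly the data-generating process the EM segmenter assumes,
which is what makes parameter-recovery and ascent tests meaningful.
`generate_lung_phantom` adds stylized geometry: two jittered elliptical lung
fields on a brighter body background and 1–3 bright nodule discs placed
fully inside the lungs (100 rejection attempts before erroring), plus
additive Gaussian noise (default sd 2 on the 8-bit scale), clamped to the
value range. Default class intensities are the two fitted tissue components
(≈60.5 lung, ≈122 tissue) plus a brighter nodule class (μ = 200, σ = 6).

What the phantoms do *not* emulate: anatomical texture, partial-volume
edges, reconstruction artifacts, 3-D continuity, scanner-specific noise
correlation, or the morphological diversity of real nodules. Tests passing
on phantoms therefore validate the algorithms' contracts and statistical
behavior, not clinical performance; headline benchmark figures on real
archives are explicitly out of scope.

## Problem sizes and test design

The test and acceptance workloads are sized for a laptop-class single CPU:
EM ascent on 20 seeded runs (K ∈ {1,2,3}, n = 5,000, 40 iterations),
parameter recovery at n = 10,000 over 10 seeds, partition metrics checked
exhaustively against brute-force oracles on all label-vector pairs up to
size 5 plus sampled pairs at size 6, the network overfit run on eight 32×32
phantoms (depth 3, 200 epochs), and the end-to-end EM pipeline on ten 64×64
two-class images whose class separation exceeds three distribution standard
deviations. These sizes keep the full suite within a few minutes while
leaving each property's failure modes observable.

## Known limitations

* The EM segmenter ignores spatial structure entirely (no smoothing or MRF
  prior); isolated misclassified pixels are expected wherever class
  densities overlap.
* Histogram-mode counting cannot detect components much rarer than the
  smoothing scale (a 5%-area nodule class rides on the tissue mode).
* The numpy network trains desk-scale models only; it has no GPU path,
  batching beyond the Adam loop, or mixed precision.
* Mixture fits with badly misspecified K converge to merged or split
  components; model-selection sweeps (AIC/BIC) are deliberately not
  included.
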