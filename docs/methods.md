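# Methods

## Signal model

All computations use the normalized mono-exponential decay

    S(η) = S0 · exp(−η / T),        η = TE / TE_max,   T = T2 / TE_max,

so a multi-echo protocol with TE = 13.2…145.2 ms maps to η ∈ {0.091, 0.182,
…, 1.0}; after discarding the first echo (stimulated-echo contamination) the
working grid is η = k/11, k = 2…11.  S0 is the (extrapolated) signal at
η = 0 in normalized intensity units; T is dimensionless.  The rate R = 1/T
is the parameter actually optimised everywhere — near-flat curves drive T to
large values where 1/T is well behaved but T itself is not.

Magnitude images carry Rician noise: complex Gaussian noise of standard
deviation σ per channel followed by a magnitude operation,
m = √((s+n_r)² + n_i²).  Its mean exceeds the noiseless value, producing a
noise floor at long echoes instead of decay to zero; that floor is the root
cause of the positive T bias of any estimator that assumes Gaussian noise.

Per-pixel SNR is defined as SNR_dB = 20·log10(‖S(η)‖₂ / (σ·√N)) with N the
number of η samples.  The denominator is read as the RMS norm of the
N-sample noise vector; with the synthesis defaults below this yields a
maximum of ≈59 dB (S0 = 1, T = 4, σ = 0.001) and −∞ where S0 = 0.  The −∞
values are kept as IEEE −inf and clipped to a −40 dB floor only inside the
binned error analysis.

## Rician expectation

The expectation of a Rician magnitude is

    E[M] = σ √(π/2) · L_{1/2}(−ν²/2σ²),

which we evaluate with exponentially scaled Bessel functions
(`scipy.special.i0e/i1e`):

    x = ν²/(2σ²),   E[M] = σ √(π/2) [ (1+x)·i0e(x/2) + x·i1e(x/2) ].

This form is overflow-safe at every SNR, so no asymptotic switch is needed;
it agrees with direct numerical integration of the Rice density to better
than 1e−6 relative over ν/σ ∈ [0, 50] (both the test suite and the
acceptance script recompute this comparison).

## Synthetic corpora

Ground-truth map pairs come in two styles with identical marginal ranges
(S0 ∈ [0,1], T ∈ [0.045, 4]) and deliberately opposite spatial statistics:

* **naturalistic** — spatially correlated grayscale images.  By default a
  procedural generator (Gaussian-smoothed random field, smoothing length
  ~H/16, plus 5–20 soft-edged random ellipses/rectangles, min-max rescaled
  to [0,1]) stands in for photographic sources; any directory of PNG/JPEG
  images can be plugged in through `source_provider`.  Each source image is
  independently min-max scaled onto its target range (per-image scaling
  maximises range coverage), grayscale conversion is the unweighted channel
  mean, and images smaller than the crop are rejected rather than resized
  (no interpolation artifacts).  A constant source image degenerates the
  min-max scale; it maps to the range midpoint with a warning.
* **urand** — i.i.d. uniform pixels.  Neighbouring pixels share no
  information, so any estimator advantage present on naturalistic data but
  absent here is attributable to learned spatial priors.

A series is synthesised by pushing a truth pair through the forward model
on the 10-echo grid and corrupting it with a single per-series
σ ~ U[0.001, 0.1] (one noise level per simulated acquisition; spatially
varying noise fields are out of scope).  Corpora are archived as HDF5
(float32, object timestamps disabled) and are byte-reproducible from a
manifest: per-series RNG streams are spawned from the master seed, so
truth maps are unique within and disjoint across corpora.

What the generator does **not** emulate: scanner reconstruction effects
(parallel-imaging noise correlation, GRAPPA artifacts), anatomy-specific
texture, B1/flip-angle errors, multi-exponential decay.  Passing tests
therefore demonstrate estimator behaviour under the stated noise model,
not clinical performance.

## Curve fitting

Four pixel-wise estimators; the log-linear result seeds the other three.

| method      | algorithm                  | parameters        | bounds |
|-------------|----------------------------|-------------------|--------|
| loglin      | OLS on ln S                | S0, R             | none   |
| nlls        | Levenberg–Marquardt        | S0, R             | none   |
| nlls_bound  | trust-region reflective    | S0, R             | S0 ∈ [0,1000], R ∈ [0.25,22] |
| nlls_rice   | trust-region reflective    | S0, R, σ_Rice     | same + σ ∈ [1e−6, 1] |

`nlls_rice` minimises the residual against E[M] rather than the noiseless
model — a least-squares approximation to Rician maximum likelihood that
needs no prior noise map.  σ_Rice starts at 0.05 (mid-range of the
synthesis distribution) and is bounded by [1e−6, 1]: the upper bound covers
the synthesis range with 10× margin; the lower bound is small enough that
the implied noise floor (~σ) cannot bias effectively noiseless fits.  An
optional two-parameter mode with σ supplied externally isolates the
Rician-model benefit from the extra-parameter cost.

Numerical choices: only non-positive samples are clamped before the log
(to 1e−6 of the series maximum) — positive samples are never floored, so
noiseless curves are fit exactly; an all-non-positive series returns a
non-converged result with R pinned at the upper bound.  Optimiser
tolerances are ftol 1e−12 / xtol 1e−14 / gtol 1e−14 with ≤400 function
evaluations: tight enough that noiseless recovery is limited by arithmetic,
cheap enough for map-scale use.  The map driver never aborts on a pixel;
failures keep the log-linear estimate and are flagged in the convergence
mask.

## Networks

Two architectures, both ending in an unconstrained 2-channel (S0, T) head:

* **nn1d** — per-pixel fully connected network: N_η inputs, 6 hidden
  layers × 64 ReLU units, 2 outputs.
* **cnn** — residual U-Net over whole series: N_η input channels, encoder
  widths (128, 128, 256, 512) at full scale, 3×3 convolutions, batch
  normalization, PReLU, residual units in the first two downsampling
  levels, skip concatenations, 1×1 output head.  Decoder upsampling is
  nearest-neighbour resize followed by a 3×3 convolution (a standard
  alternative to transposed convolution that avoids checkerboard
  artifacts and keeps the backward pass simple).

The layers, backpropagation and AdamW optimiser (lr 0.002, betas
0.9/0.999, weight decay 0.01) are implemented directly on numpy in this
package; training is bitwise deterministic for a fixed seed.  The output
head's bias is initialised at (S0, T) = (0.5, 1.0): with T initialised
near zero the self-supervised forward model exp(−η/T) has vanishing
gradients and the T channel never trains.  Inside the self-supervised loss
T is clipped to [0.01, 100] (straight-through gradient) before entering
the forward model.

Training strategies: *supervised* (MSE against ground-truth S0/T maps —
the network implicitly learns the Rician statistics because noisy inputs
are paired with clean labels) and *self-supervised* (MSE between the
forward-modelled prediction and the measured series; no labels).  The
self-supervised loss contains no Rician correction term, so those models
inherit the positive low-SNR T bias of Gaussian least squares.  Series are
split 80/20 train/validation for monitoring only — no early stopping —
with the best-validation-epoch weights additionally snapshotted.  No
output clipping is applied at inference by default: range restriction is
learned from the training distribution.

Two named profiles exist.  `paper` is the full-scale configuration
(128×128 maps, widths (128,128,256,512), 10,000 series, 1000 CNN epochs);
it is provided for completeness and is not exercised by the test suite.
`desk` — used by every comparison experiment here — runs 32×32 maps,
widths (16,16,32,64), 300 naturalistic training series (240 train / 60
validation), CNN: 40 epochs × batch 10, NN1D: 40 epochs × batch 2048
(~4.8k optimizer steps, comparable to the full-scale step count).  These
sizes keep a complete ordering experiment within minutes on one CPU while
preserving the mechanisms being compared.

## Evaluation

Per-slice metrics over the signed error T_pred − T_true: **bias** =
median, **precision** = IQR (75th − 25th percentile), **accuracy** =
median absolute error; plus SSIM between predicted and true maps.  SSIM
uses a uniform 7×7 window, K1 = 0.01 / K2 = 0.03, and a *fixed*
data_range of 4.0 (the span of the T range) so scores are comparable
across methods and series.  Metrics are computed over all pixels with no
tissue mask; an optional ROI mask supports regional analyses.

The per-pixel binned analysis buckets signed errors into 100 equal-width
bins over SNR (floored at −40 dB; S0 = 0 pixels land in the lowest bin)
and over T_true, reporting per-bin medians and IQRs and the 2D surface;
bin counts conserve the number of records.

The noise-addition experiment corrupts each (already magnitude) series
with additional complex Gaussian noise of σ_add ∈ {0.02 … 0.08} followed
by a magnitude operation, re-estimates without retraining, and compares
each method to its own zero-added-noise reference map — so it measures
robustness without requiring ground truth.

## Degenerate inputs and tie-breaks

All-zero pixels: log-linear flags non-convergence and pins R at its upper
bound; bounded fits return estimates on the bounds with the `at_bound`
flag set.  Constant source images map to range midpoints with a warning.
Grid mismatches between a trained model and input series raise with both
grids printed.  Center crops use the floor convention for odd margins.

## Known limitations

The numpy network engine is single-threaded and desk-scale only; the
`paper` profile is declared but not practical without accelerator-backed
training.  The synthetic corpus uses one σ per series, so spatially
varying noise (the main obstacle to per-pixel Rician ML fitting in vivo)
is represented only implicitly.  Self-supervised CNN training at desk
scale is supported but slower to converge than its supervised
counterpart; comparisons here use the supervised CNN and self-supervised
NN1D as the representative pair.  DICOM ingestion handles mainstream
single-frame series with EchoTime tags; vendor private tags are ignored.
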