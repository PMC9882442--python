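# t2relax

Quantitative T2 relaxometry toolkit for multi-echo magnitude MRI: it
synthesises physics-based training/test data with known ground truth,
estimates per-pixel (S0, T) maps with four curve-fitting methods and with
neural networks (per-pixel 1D and convolutional U-Net, trained supervised
or self-supervised), and compares estimators quantitatively by bias,
precision, accuracy, SSIM and noise robustness.

It is aimed at quantitative-MRI researchers who fit mono-exponential decay
to previously reconstructed magnitude images — T2 mapping in particular,
but the normalized formulation applies to any mono-exponential process.

## The model

A multi-echo series is described by

    S(η) = S0 · exp(−η / T),      η = TE / TE_max,   T = T2 / TE_max,

with Rician measurement noise: complex Gaussian noise of scale σ per
channel followed by a magnitude operation.  Because the Rician mean
plateaus at ~σ√(π/2) instead of decaying to zero, least-squares estimators
that assume Gaussian noise overestimate T wherever SNR is low
(SNR_dB = 20 log10(‖S(η)‖₂ / σ√N)).  The package implements:

* **fitting** — `loglin` (OLS on ln S, also the initialiser), `nlls`
  (Levenberg–Marquardt), `nlls_bound` (trust-region reflective with
  S0 ∈ [0,1000], 1/T ∈ [0.25,22]), and `nlls_rice` (three-parameter fit
  against the Rician expected magnitude
  E[M] = σ√(π/2)·L½(−ν²/2σ²));
* **synthetic** — spatially correlated ("naturalistic") and pixel-random
  ("urand") ground-truth corpora with per-series σ ~ U[0.001, 0.1];
* **networks** — a self-contained numpy neural-network engine (dense and
  convolutional layers, manual backprop, AdamW) powering a per-pixel MLP
  and a residual U-Net, trainable with supervised (MSE vs ground truth) or
  self-supervised (MSE vs the forward-modelled measurement) losses;
* **evaluation** — per-slice bias / precision / accuracy (median signed
  error / IQR / median absolute error), SSIM, SNR- and T-binned error
  tables, and a noise-addition robustness experiment.

## Worked example

Fit one synthetic naturalistic series (32×32, 10 echoes) with all four
methods and score against the known truth:

```python
from t2relax.synthetic import DatasetManifest, generate_dataset
from t2relax.fitting import fit_image_series
from t2relax.evaluation import ErrorMaps, slice_summary

ds = generate_dataset(DatasetManifest(n_series=1, shape=(32, 32),
                                      style="naturalistic", master_seed=7))
sample = ds.sample(0)
print(f"series sigma = {sample.sigma:.4f}")
for method in ("loglin", "nlls", "nlls_bound", "nlls_rice"):
    pmap = fit_image_series(sample.series, method=method)
    m = slice_summary(ErrorMaps(pmap.t, sample.truth.t_map))
    print(f"{method:11s} bias={m.bias:+.4f} precision={m.precision:.4f} "
          f"accuracy={m.accuracy:.4f} ssim={m.ssim:.3f}")
```

Output:

```
series sigma = 0.0275
loglin      bias=-0.0147 precision=0.3902 accuracy=0.1960 ssim=0.418
nlls        bias=-0.0120 precision=0.3516 accuracy=0.1790 ssim=0.430
nlls_bound  bias=-0.0039 precision=0.3688 accuracy=0.1790 ssim=0.588
nlls_rice   bias=-0.1894 precision=0.8354 accuracy=0.3270 ssim=0.393
```

Bias is the per-slice median of T_pred − T_true (here near zero for the
Gaussian-loss fits at this moderate noise level), precision the IQR of
that signed error, accuracy the median |T_pred − T_true|, and SSIM the
structural similarity to the true T map.  Bounding the fit improves SSIM
by suppressing wild estimates in low-SNR pixels; the three-parameter Rice
fit pays for its extra parameter with worse precision — both effects grow
with noise.

A command-line surface mirrors the library
(`t2relax generate|fit|train|predict|evaluate|noise-exp|ingest|pipeline`);
`t2relax pipeline src/t2relax/configs/desk_urand.yaml` runs a small
end-to-end smoke study.  Real acquisitions enter through
`t2relax.io.ingest_invivo` (DICOM directory or 4D NIfTI; first echo
discarded, center-cropped to 128×128, max-normalized).

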