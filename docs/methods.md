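# Methods

## Signal model

All estimators in this package assume mono-exponential magnitude decay in a
normalized sampling dimension,

    S(eta) = S0 * exp(-eta / T),

where `eta = TE / TE_max` is the echo time normalized by the maximum echo
time, `T = T2 / TE_max` is the normalized time constant, and `S0` is the
signal at `eta = 0`. The normalization makes the model dimensionless, so the
same code describes any mono-exponential process sampled on a finite grid.
For the 11-echo acquisition the package targets (TE = 13.2..145.2 ms in
13.2 ms steps, first echo discarded to reduce stimulated-echo contamination),
the retained grid is `eta = k/11, k = 2..11` and `TE_max = 145.2 ms`, so a
normalized `T = 1` corresponds to `T2 = 145.2 ms`.

Internally all iterative fits parameterize the decay by the rate `R = 1/T`;
this avoids division-by-zero pathologies and makes the box bounds linear in
the fitted parameter. `T = 0` inputs are rejected rather than mapped to zero
signal.

## Noise model

Magnitude images formed from complex data with additive Gaussian noise in
each channel carry Rician noise: a pixel with true magnitude `nu` and
channel noise `sigma` is observed as `|nu + g1 + i*g2|`,
`g1, g2 ~ N(0, sigma^2)`. The observed signal does not decay to zero but
plateaus near `sigma * sqrt(pi/2)`, which is why plain least squares
overestimates `T` at low SNR.

The expectation of the observed magnitude has the closed form

    E[M] = sigma * sqrt(pi/2) * L_{1/2}(-nu^2 / (2 sigma^2)),

with the generalized Laguerre function `L_{1/2}` evaluated through
exponentially scaled modified Bessel functions:

    E[M] = sigma * sqrt(pi/2) * e^{-z} [(1 + 2z) I0(z) + 2z I1(z)],
    z = nu^2 / (4 sigma^2).

For `nu/sigma > 40` the implementation switches to the asymptotic expansion
`E[M] ~ nu + sigma^2 / (2 nu)`; at the switch point the two branches agree
to better than 1e-7 relative, and the scaled-Bessel form is overflow-free
below it. `sigma = 0` returns `nu` exactly.

Per-pixel SNR is defined over the whole echo series,

    SNR_dB = 20 log10( ||S(eta)||_2 / (sigma * sqrt(N)) ),

with `N` the number of echoes. Pixels with `S0 = 0` have SNR `-inf`; the
sentinel propagates through the analysis code and such pixels fall out of
every finite histogram bin. Under the synthesis distribution below the
attainable maximum is 58.75 dB (`S0 = 1`, `T = 4`, `sigma = 0.001`), i.e.
59 dB to the nearest integer.

## Synthetic data

Synthetic training/testing series emulate the acquisition: 128 x 128
ground-truth maps with `S0` in [0, 1] and `T` in [0.045, 4], forward
simulation on `eta = k/11, k = 2..11`, then Rician corruption with a
per-series channel noise `sigma ~ Uniform[0.001, 0.1]`. `T = 0.045 = 1/22.2`
to `T = 4` corresponds to 6.6-580.8 ms at `TE_max = 145.2 ms` - 0.25x the
shortest retained echo time up to 4x the longest - bracketing tissue values
with a wide margin so that supervised estimators trained on this range are
not biased by a too-narrow prior.

Two ground-truth distributions are provided:

* **corpus mode** - each record consumes two distinct grayscale images from
  an image corpus (one becomes `S0`, one becomes `T`), center-cropped and
  min-max scaled *per image* onto the parameter range. Per-image scaling is a
  deliberate choice (a corpus-global scaling would leave many maps spanning
  only part of the range); it guarantees every record exercises the full
  parameter interval. Images smaller than the target size are bicubically
  upsampled before cropping; color images are averaged over channels
  (luminance weighting is irrelevant to the statistics that matter here);
  constant images degenerate to the range midpoint with a warning.
* **urand mode** - every pixel of `S0` and `T` is drawn i.i.d. uniform.
  These maps have (lag-1) spatial autocorrelation ~ 0, so an estimator that
  exploits neighboring pixels gains nothing on them.

The contrast between the two is the instrument for isolating learned
*spatial priors*: convolutional estimators can denoise by averaging over
spatially correlated neighborhoods on corpus-style data but not on urand
data.

Instead of a downloaded photographic corpus, the package ships a
**procedural corpus generator**: Gaussian random fields at two length scales
overlaid with constant-intensity ellipses and rectangles, clipped to [0, 1].
It reproduces the properties the synthesis pipeline actually relies on -
smooth gradients, texture, piecewise-constant regions, strong spatial
autocorrelation (lag-1 > 0.5) - and is deterministic given a seed, so the
whole repository is testable without any download. A directory of PNG/JPEG
photographs can be substituted wherever a corpus is accepted. What the
generator does **not** emulate: the long-tailed intensity statistics and
semantic structure of photographs, spatially varying noise from parallel
imaging, stimulated-echo contamination, or multi-exponential decay. Passing
tests on this corpus therefore demonstrate the estimation machinery and the
spatial-prior mechanism, not in vivo image fidelity.

Noiseless synthetic series are not re-normalized after noise addition; the
global-max normalization convention applies to measured in vivo data (where
intensities are arbitrary), not to the simulation (where `S0 <= 1` by
construction).

## Curve fitting

Four per-pixel estimators:

| method           | algorithm                    | parameters            | bounds        |
|------------------|------------------------------|-----------------------|---------------|
| `fit_loglin`     | OLS on `ln S` vs `eta`       | `S0, R`               | none          |
| `fit_nlls`       | Levenberg-Marquardt          | `S0, R`               | none          |
| `fit_nlls_bound` | trust region reflective      | `S0, R`               | `S0` [0,1000], `R` [0.25,22] |
| `fit_nlls_rice`  | trust region reflective      | `S0, R, sigma_rice`   | same + `sigma` [0,10] |

The log-linear fit uses one shared design matrix for all pixels (a single
`lstsq` call); nonpositive samples are clamped to a machine-epsilon-scaled
floor before the log, keeping the fit total and vectorized. No weighting is
applied, so the log transform implicitly over-weights high-signal points -
this is the standard, uncorrected practice. Its estimates seed all iterative
fits.

The iterative fits run per pixel with analytic Jacobians (2-parameter
methods) or 2-point numeric differences (the 3-parameter Rician fit), with
relative tolerances 1e-8 and at most 100 function evaluations per pixel.
Non-convergent pixels keep their initial (log-linear) estimate and are
flagged in `FitResult.converged`. The bound `R` in [0.25, 22] is exactly
`T` in [0.045, 4]; `T = 1/R` is reported even at active bounds, so a
non-decaying curve pins at `T = 4`. `fit_nlls_rice` minimizes the residual
against the *expectation value* of the Rician distribution - not a full
maximum-likelihood fit, which is numerically unstable per pixel - and
initializes `sigma` from the log-linear RMS residual.

Residual-based noise estimation (`estimate_sigma_map`) uses the
degrees-of-freedom-corrected RMS residual, `sqrt(SS / (n - 2))`, which feeds
the SNR formula when the true noise level is unknown.

## Neural estimators

Because no deep-learning framework is a dependency of this package, the two
architectures are implemented in a small self-contained NumPy layer kit
(im2col convolutions, batch normalization, PReLU, manual backpropagation,
AdamW) that is gradient-checked against numeric differentiation in the test
suite.

**NN1D** - a per-pixel multilayer perceptron: 10 echo magnitudes in, (S0, T)
out, layer stack 10->64, 4 x (64->64), 64->2 with ReLU between weight
layers; 17,474 trainable parameters exactly. Stated descriptions of this
architecture ("6 hidden layers of 64") are ambiguous; the parameter count
pins the stack as listed.

**CNN** - a residual U-Net for whole-series map regression: 10 input
channels, 2 output channels, encoder widths (128, 128, 256, 512) with three
stride-2 stages, 3 x 3 convolutions throughout, two-convolution residual
units in the encoder (strided residual projections where shape changes,
1 x 1 where only width changes), concatenating skip connections, transposed
3 x 3 convolutions for upsampling each followed by a single-convolution
residual unit, batch normalization and PReLU everywhere except the linear
output head. The reference configuration has **6,950,457** trainable
parameters, i.e. 6.9 M as commonly quoted (truncated); the layer table is
exactly reproducible from `decaymap/nn/models.py`. Regression targets are
unbounded, so neither network has an output activation.

Training is supervised MSE against the ground-truth (S0, T) maps with AdamW
(lr 0.002, weight decay 0.01). The 1-D network consumes pixel curves
extracted record-major/row-major; the CNN consumes whole series. Records are
split 80/20 into train/validation at the series level and the
best-validation weights are kept (final weights are also recoverable from a
checkpoint's history). Reference recipes are 5 epochs x batch 10,000 curves
(NN1D) and 1000 epochs x batch 100 series (CNN); both scale down freely. A
trained model is locked to its echo schedule: predictions on a different
grid raise instead of silently interpolating.

### Scaled-down study preset

`decaymap.presets.train_scaled_down_models` runs the full pipeline at sizes
chosen for a single CPU: 32 x 32 maps, a narrow U-Net (widths 16, 16, 32,
64; ~113 k parameters), 240 corpus training series for 60 epochs at batch 8,
an NN1D trained on 100 urand series for 40 epochs, and 50-series held-out
corpus/urand test sets built from disjoint corpus partitions and seeds. At
these sizes the pipeline trains in about a minute and reproduces the
qualitative findings: the corpus-trained CNN roughly halves the median
per-slice |T error| of unbounded NLLS on corpus-style test data, the
advantage reverses on urand test data, and the CNN is the most robust method
under added noise.

One caveat at this scale: *training-range confinement* (predictions staying
inside the training `T` range on wild inputs) is exact for the trained NN1D
(all predictions within [-0.5, 5]) but only soft for the small CNN - on
non-decaying inputs its outputs stay bounded near the training range
(< ~2x the upper bound) where the unbounded fit diverges, but a minority of
pixels exceed 5. Wider training (the reference configuration) tightens this.

## Evaluation conventions

Per-slice summaries of a `T` map against a reference use the signed error
`T_pred - T_true`: **bias** = median, **precision** = interquartile range,
**accuracy** = median absolute error. Medians and IQRs are order statistics,
so these summaries are invariant to pixel permutation; SSIM is not.

SSIM uses the dominant convention: single-scale, Gaussian 11 x 11 window
with sigma 1.5, population (not sample) covariance, stability constants
K1 = 0.01 / K2 = 0.03, and a *fixed* data range of 3.955 (the span of the
`T` synthesis range) so that scores are comparable across slices. Maps
smaller than 11 pixels shrink the window to the largest odd size that fits.
Two identical maps score 1.0 by convention, including constant maps.

Binned error surfaces divide the observed finite range of each axis (SNR in
dB and `T_true`) into 100 equal-width bins, half-open `[lo, hi)` with the
final bin closed, and record the median/IQR/count of the signed error per
bin, both marginally and jointly. Empty bins hold NaN, not zero. `-inf` SNR
pixels (where `S0 = 0`) are excluded before binning.

The noise-addition experiment adds complex Gaussian noise of
`sigma = 0.02..0.08` (presets: 0.01 steps, or the short 0.02/0.03/0.04
grid) to normalized series, re-estimates maps with each method *without
retraining*, and summarizes each method against its own maps from the
original data - so the zero-added-noise row is identically perfect and the
metrics measure degradation, not absolute error. Input series must be
normalized because the added-noise units are relative to a global max of
1.0.

## Degenerate inputs and tie-breaks

* All-zero series cannot be normalized (error); constant corpus images map
  to the range midpoint (warning).
* Center crops with odd excess take the extra pixel at the trailing edge
  (leading offset `floor((dim - crop)/2)`).
* Normalization is applied before cropping for measured data, so a cropped
  series' max may fall slightly below 1.0; the `normalized` flag is carried
  through.
* Noise streams are derived per series from the dataset seed, so any record
  is reproducible in isolation.
* Fits that fail to converge never crash a map: they fall back to the
  log-linear start and are flagged.

## Known limitations

* Magnitude-only inputs; no complex- or real-valued fitting.
* Mono-exponential model only; no stimulated-echo / Bloch-simulation echo
  modulation, no multi-exponential decay.
* Trained networks apply only to the echo grid they were trained on.
* The procedural corpus is a stand-in for photographic corpora (synthetic by
  construction); conclusions about in vivo performance require in vivo data,
  which the evaluation harness accepts but never requires.
* No Bayesian or dictionary-based estimation, and no full Rician maximum
  likelihood.
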