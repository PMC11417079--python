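# decaymap

Quantitative parameter mapping from multi-echo magnitude MRI. `decaymap`
estimates per-pixel maps of the signal amplitude `S0` and the normalized
decay constant `T` from a series of magnitude images following
mono-exponential decay,

    S(eta) = S0 * exp(-eta / T),        eta = TE / TE_max,  T = T2 / TE_max,

as acquired in T2 relaxometry (and, with reinterpretation of `eta`, other
mono-exponential problems such as diffusion). It is aimed at researchers who
fit previously reconstructed magnitude image series - the routinely archived
output of clinical scanners - where the noise is Rician, not Gaussian, and
pixelwise least squares therefore overestimates `T` at low SNR.

The package provides, under one roof:

* **Curve fitting** - the four standard per-pixel estimators: log-linear
  regression, unbounded Levenberg-Marquardt least squares, bounded
  trust-region least squares (`T` restricted to [0.045, 4]), and a
  three-parameter fit against the Rician expectation value
  `E[M] = sigma sqrt(pi/2) L_{1/2}(-nu^2/2sigma^2)`.
* **Physics-based synthetic data** - forward-simulated image series with
  known ground truth, Rician noise with per-series `sigma ~ U[0.001, 0.1]`,
  and two ground-truth distributions: spatially correlated maps built from
  an image corpus (a procedural generator is included, so nothing needs to
  be downloaded) and spatially uncorrelated pixelwise-uniform maps.
* **Neural estimators** - a per-pixel MLP (17,474 parameters) and a
  residual U-Net (6.9 M parameters at the reference width), implemented in
  a self-contained NumPy layer kit and trained supervised (MSE, AdamW) on
  the synthetic data.
* **Evaluation harness** - per-slice bias (median signed `T` error),
  precision (IQR), accuracy (median |error|), SSIM; per-pixel error surfaces
  binned on SNR and `T_true` (100 bins); and a noise-addition robustness
  experiment.

The per-pixel SNR convention is
`SNR_dB = 20 log10(||S(eta)||_2 / (sigma sqrt(N)))`, which spans -inf (where
`S0 = 0`) to 58.75 dB over the synthetic data distribution.

## Worked example

Simulate one corpus-style slice with known ground truth, fit it with the
bounded least-squares estimator, and score the result:

```python
import decaymap as dm
from decaymap.model import MonoExpDecayModel

corpus = dm.procedural_corpus(2, size=64, seed=0)
rec = dm.build_synthetic_dataset(
    dm.SynthConfig(n_series=1, size=64, mode="corpus", seed=0), corpus=corpus
)[0]

res = MonoExpDecayModel(rec.series).fit(method="nlls_bound")
print(res.summary())
summ = dm.summarize_errors(res.params, rec.truth)
print(summ)
```

which prints

```
Mono-exponential decay fit
==========================
method:            fit_nlls_bound
spatial shape:     (64, 64)
echoes:            10
converged:         100.0% of pixels
T   median [IQR]:  1.3131 [0.7040, 1.9281]
S0  median [IQR]:  0.4780 [0.3317, 0.6925]
residual RMS med:  2.310e-02
ErrorSummary(bias=0.0263..., precision=0.2407..., accuracy=0.1194..., ssim=0.5958...)
```

Every pixel converged inside the physical bounds; the residual RMS
(~0.023) matches this record's simulated noise level (`rec.sigma` = 0.0277),
and the per-slice summary says the fit is nearly unbiased (bias 0.026 in
normalized `T` units) with a median absolute `T` error of 0.12 - typical
least-squares behavior at this moderate noise level. On an 11-echo
145.2 ms acquisition, a normalized `T` of 1.31 corresponds to
`T2 = 190 ms` (`res.t2_ms_map()`).

To reproduce the study's headline comparison at CPU scale - a small U-Net
trained on 240 synthetic corpus series that roughly halves the median
per-slice `T` error of unbounded least squares on correlated test data, but
loses that advantage on uncorrelated data -

```python
from decaymap.presets import train_scaled_down_models
out = train_scaled_down_models(seed=11)   # ~1 minute on one CPU
```

The same pipeline is scriptable from the shell: `decaymap synth`, `fit`,
`train`, `predict`, `eval`, `noise-exp` (see `decaymap --help`).

## Layout

```
src/decaymap/
  core.py       signal model, Rician noise, SNR, preprocessing
  synth.py      synthetic datasets + procedural image corpus
  fitting.py    the four curve fitters, Rician mean, noise estimation
  model.py      MonoExpDecayModel / MonoExpDecayResults (fit surface)
  nn/           NumPy layer kit, MLP + U-Net builders, AdamW, training
  presets.py    CPU-scale end-to-end study preset
  evaluate.py   bias/precision/accuracy, SSIM, binned surfaces, noise exp
  io.py         NIfTI (+JSON sidecar), HDF5 containers, checkpoints
  cli.py        command-line interface
docs/methods.md   model, conventions, design choices, limitations
```
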