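"""Quantitative comparison machinery for T-map estimators.

Per-slice error decomposition follows the bias / precision / accuracy
convention for parameter maps:

* **bias** — median of the signed error T_pred - T_true,
* **precision** — interquartile range (75th - 25th percentile) of the signed
  error (smaller is better),
* **accuracy** — median of the absolute error |T_pred - T_true|,

plus the structural similarity index (SSIM) between the maps.  Per-pixel
errors can be binned on SNR and T_true axes (100 bins each) to resolve where
in the (SNR, T) plane an estimator is biased.  The noise-addition experiment
measures robustness by re-estimating maps after Rician noise augmentation and
comparing each method against its own maps from the original data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .core import ImageSeries, NoiseSpec, ParameterMap, add_rician_noise

__all__ = [
    "ErrorSummary",
    "BinnedErrorSurface",
    "NoiseRobustnessResult",
    "summarize_errors",
    "ssim_score",
    "bin_errors",
    "noise_addition_experiment",
    "T_DATA_RANGE",
]

# SSIM data range: span of the T synthesis/training range [0.045, 4]
T_DATA_RANGE = 4.0 - 0.045


@dataclass(frozen=True)
class ErrorSummary:
    """Per-slice error decomposition of a T map against a reference."""

    bias: float
    precision: float
    accuracy: float
    ssim: float

    def as_dict(self) -> dict:
        return {
            "bias": self.bias,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "ssim": self.ssim,
        }


def ssim_score(pred: np.ndarray, truth: np.ndarray, data_range: float = T_DATA_RANGE) -> float:
    """Single-scale SSIM, Gaussian 11 x 11 window (sigma 1.5), fixed data range.

    Symmetric in its arguments; identical maps (including two equal constant
    maps) score 1.0.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("maps must have matching shapes")
    if np.array_equal(pred, truth):
        return 1.0
    win = min(11, min(pred.shape))
    if win % 2 == 0:
        win -= 1  # window must be odd; shrink only for maps below 11 pixels
    return float(
        structural_similarity(
            truth,
            pred,
            gaussian_weights=True,
            sigma=1.5,
            win_size=win,
            use_sample_covariance=False,
            data_range=data_range,
        )
    )


def summarize_errors(
    pred: ParameterMap, truth: ParameterMap, mask: np.ndarray | None = None
) -> ErrorSummary:
    """Bias / precision / accuracy over (masked) pixels of the T maps + SSIM."""
    if pred.shape != truth.shape:
        raise ValueError("maps must have matching shapes")
    err = pred.t - truth.t
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != err.shape:
            raise ValueError("mask shape mismatch")
        if not mask.any():
            raise ValueError("mask selects no pixels")
        vals = err[mask]
    else:
        vals = err.reshape(-1)
    q25, q50, q75 = np.percentile(vals, [25, 50, 75])
    return ErrorSummary(
        bias=float(q50),
        precision=float(q75 - q25),
        accuracy=float(np.median(np.abs(vals))),
        ssim=ssim_score(pred.t, truth.t),
    )


@dataclass
class BinnedErrorSurface:
    """Median/IQR of signed error binned on SNR and T_true axes.

    Equal-width bins span the observed finite range of each axis; the binning
    is half-open [lo, hi) with the final bin closed.  Empty bins hold NaN.
    Pixels with non-finite SNR (S0 = 0 gives -inf) are excluded everywhere.
    """

    snr_edges: np.ndarray
    t_edges: np.ndarray
    median_vs_snr: np.ndarray
    iqr_vs_snr: np.ndarray
    counts_vs_snr: np.ndarray
    median_vs_t: np.ndarray
    iqr_vs_t: np.ndarray
    counts_vs_t: np.ndarray
    median_2d: np.ndarray
    iqr_2d: np.ndarray
    counts_2d: np.ndarray

    @property
    def n_finite(self) -> int:
        return int(self.counts_2d.sum())


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.digitize(values, edges) - 1
    # final bin is closed: values exactly at the upper edge belong to it
    idx[values == edges[-1]] = len(edges) - 2
    return idx


def _grouped_stats(idx: np.ndarray, err: np.ndarray, n_bins: int):
    med = np.full(n_bins, np.nan)
    iqr = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    order = np.argsort(idx, kind="stable")
    idx_s, err_s = idx[order], err[order]
    bounds = np.searchsorted(idx_s, np.arange(n_bins + 1))
    for b in range(n_bins):
        lo, hi = bounds[b], bounds[b + 1]
        if hi > lo:
            seg = err_s[lo:hi]
            q25, q50, q75 = np.percentile(seg, [25, 50, 75])
            med[b], iqr[b], counts[b] = q50, q75 - q25, hi - lo
    return med, iqr, counts


def bin_errors(
    signed_error: np.ndarray,
    snr: np.ndarray,
    t_true: np.ndarray,
    n_bins: int = 100,
) -> BinnedErrorSurface:
    """Bin per-pixel signed errors into 1-D marginals and the joint surface."""
    err = np.asarray(signed_error, dtype=float).reshape(-1)
    snr = np.asarray(snr, dtype=float).reshape(-1)
    t = np.asarray(t_true, dtype=float).reshape(-1)
    if not (err.shape == snr.shape == t.shape):
        raise ValueError("inputs must have matching shapes")
    finite = np.isfinite(snr) & np.isfinite(err) & np.isfinite(t)
    if not finite.any():
        raise ValueError("no pixels with finite SNR")
    err, snr, t = err[finite], snr[finite], t[finite]

    snr_edges = np.linspace(snr.min(), snr.max(), n_bins + 1)
    t_edges = np.linspace(t.min(), t.max(), n_bins + 1)
    if snr_edges[0] == snr_edges[-1]:
        snr_edges = snr_edges + np.linspace(0, 1e-9, n_bins + 1)
    if t_edges[0] == t_edges[-1]:
        t_edges = t_edges + np.linspace(0, 1e-9, n_bins + 1)
    si = _bin_index(snr, snr_edges)
    ti = _bin_index(t, t_edges)

    med_s, iqr_s, cnt_s = _grouped_stats(si, err, n_bins)
    med_t, iqr_t, cnt_t = _grouped_stats(ti, err, n_bins)
    joint = si * n_bins + ti
    med_j, iqr_j, cnt_j = _grouped_stats(joint, err, n_bins * n_bins)
    return BinnedErrorSurface(
        snr_edges=snr_edges,
        t_edges=t_edges,
        median_vs_snr=med_s,
        iqr_vs_snr=iqr_s,
        counts_vs_snr=cnt_s,
        median_vs_t=med_t,
        iqr_vs_t=iqr_t,
        counts_vs_t=cnt_t,
        median_2d=med_j.reshape(n_bins, n_bins),
        iqr_2d=iqr_j.reshape(n_bins, n_bins),
        counts_2d=cnt_j.reshape(n_bins, n_bins),
    )


# default added-noise grid: the 0.02-0.08 range at 0.01 steps
SIGMA_LEVELS_FULL = (0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08)
# the three illustrative levels
SIGMA_LEVELS_SHORT = (0.02, 0.03, 0.04)


@dataclass
class NoiseRobustnessResult:
    """Tidy per-(series, method, sigma) error summaries.

    The reference map for each method at each level is the *same method's*
    map from the original (no added noise) series, so level 0 is identically
    perfect by construction.
    """

    frame: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Median over series of each metric, per method and noise level."""
        return (
            self.frame.groupby(["method", "sigma_added"])[
                ["bias", "precision", "accuracy", "ssim"]
            ]
            .median()
            .reset_index()
        )


def noise_addition_experiment(
    dataset: Sequence[ImageSeries],
    methods: Mapping[str, Callable[[ImageSeries], ParameterMap]],
    sigma_levels: Sequence[float] = SIGMA_LEVELS_FULL,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> NoiseRobustnessResult:
    """Measure each method's sensitivity to retrospectively added Rician noise.

    All series must be normalized (added sigma is in units of the global max).
    Estimators are applied as-is — no retraining.  Noise draws are
    reproducible from ``seed`` with an independent stream per (series, level).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, series in enumerate(dataset):
        if not series.normalized:
            raise ValueError(
                "noise-addition experiment requires normalized series "
                "(sigma units are relative to a global max of 1.0)"
            )
        baselines = {name: fn(series) for name, fn in methods.items()}
        for sigma in sigma_levels:
            noise_seed = int(rng.integers(0, 2**31 - 1))
            augmented = add_rician_noise(series, NoiseSpec(sigma=sigma, seed=noise_seed))
            for name, fn in methods.items():
                summ = summarize_errors(fn(augmented), baselines[name], mask=mask)
                rows.append(
                    {"series": i, "method": name, "sigma_added": sigma, **summ.as_dict()}
                )
    return NoiseRobustnessResult(frame=pd.DataFrame(rows))
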