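"""Model/Results surface over the per-pixel curve fitters.

``MonoExpDecayModel`` holds one multi-echo magnitude series; ``fit`` runs a
chosen estimator and returns ``MonoExpDecayResults`` carrying the parameter
maps, per-pixel diagnostics, derived quantities (noise map, SNR map, physical
T2), and a text ``summary()``.

    >>> model = MonoExpDecayModel.from_arrays(data, te_ms=13.2 * np.arange(1, 12))
    >>> res = model.fit(method="nlls_bound")
    >>> print(res.summary())
"""

from __future__ import annotations

import numpy as np

from .core import EchoSchedule, ImageSeries, normalize_series, snr_db
from .fitting import (
    FitBounds,
    FitResult,
    estimate_sigma_map,
    fit_loglin,
    fit_nlls,
    fit_nlls_bound,
    fit_nlls_rice,
)

__all__ = ["MonoExpDecayModel", "MonoExpDecayResults", "FIT_METHODS"]

FIT_METHODS = {
    "loglin": fit_loglin,
    "nlls": fit_nlls,
    "nlls_bound": fit_nlls_bound,
    "nlls_rice": fit_nlls_rice,
}


class MonoExpDecayModel:
    """A mono-exponential decay model S(eta) = S0 exp(-eta/T) for one series."""

    def __init__(self, series: ImageSeries):
        self.series = series

    @classmethod
    def from_arrays(
        cls,
        data: np.ndarray,
        eta: np.ndarray | None = None,
        te_ms: np.ndarray | None = None,
        normalize: bool = False,
    ) -> "MonoExpDecayModel":
        """Build from a raw height x width x n stack plus its sampling grid."""
        if (eta is None) == (te_ms is None):
            raise ValueError("provide exactly one of eta or te_ms")
        sched = (
            EchoSchedule(eta=np.asarray(eta, dtype=float))
            if eta is not None
            else EchoSchedule.from_te_ms(te_ms)
        )
        series = ImageSeries(np.asarray(data, dtype=float), sched)
        if normalize:
            series = normalize_series(series)
        return cls(series)

    def fit(self, method: str = "nlls", **kwargs) -> "MonoExpDecayResults":
        """Fit every pixel with one of loglin | nlls | nlls_bound | nlls_rice."""
        try:
            fitter = FIT_METHODS[method]
        except KeyError:
            raise ValueError(
                f"unknown method {method!r}; choose from {sorted(FIT_METHODS)}"
            ) from None
        return MonoExpDecayResults(self, fitter(self.series, **kwargs))


class MonoExpDecayResults:
    """Estimated parameter maps with uncertainties and diagnostics."""

    def __init__(self, model: MonoExpDecayModel, fit: FitResult):
        self.model = model
        self.fit = fit

    @property
    def params(self):
        return self.fit.map

    @property
    def s0_map(self) -> np.ndarray:
        return self.fit.map.s0

    @property
    def t_map(self) -> np.ndarray:
        return self.fit.map.t

    @property
    def r_map(self) -> np.ndarray:
        return self.fit.map.r

    @property
    def method(self) -> str:
        return self.fit.method

    def t2_ms_map(self) -> np.ndarray:
        """Physical T2 in milliseconds (requires TE metadata on the schedule)."""
        te_max = self.model.series.schedule.te_max_ms
        if te_max is None:
            raise ValueError("schedule carries no physical TE information")
        return self.t_map * te_max

    def sigma_map(self) -> np.ndarray:
        """Residual-based per-pixel noise estimate (RMS residual, dof n - 2)."""
        return estimate_sigma_map(self.model.series, self.fit)

    def snr_db_map(self, sigma=None) -> np.ndarray:
        """Per-pixel SNR in dB; sigma defaults to the residual-based estimate."""
        if sigma is None:
            sigma = np.maximum(self.sigma_map(), np.finfo(float).tiny)
        t = np.maximum(self.t_map, np.finfo(float).tiny)  # unbounded fits can stray
        return snr_db(self.s0_map, t, sigma, self.model.series.schedule)

    def summary(self) -> str:
        t = self.t_map[np.isfinite(self.t_map)]
        s0 = self.s0_map[np.isfinite(self.s0_map)]
        rms = self.fit.residual_rms
        q = lambda a, p: float(np.percentile(a, p)) if a.size else float("nan")
        lines = [
            "Mono-exponential decay fit",
            "==========================",
            f"method:            {self.method}",
            f"spatial shape:     {self.fit.map.shape}",
            f"echoes:            {self.model.series.schedule.n}",
            f"converged:         {100.0 * self.fit.converged.mean():.1f}% of pixels",
            f"T   median [IQR]:  {q(t, 50):.4f} [{q(t, 25):.4f}, {q(t, 75):.4f}]",
            f"S0  median [IQR]:  {q(s0, 50):.4f} [{q(s0, 25):.4f}, {q(s0, 75):.4f}]",
            f"residual RMS med:  {float(np.median(rms)):.3e}",
        ]
        if self.fit.map.sigma_rice is not None:
            sr = self.fit.map.sigma_rice
            lines.append(f"sigma_rice median: {float(np.median(sr)):.4f}")
        te_max = self.model.series.schedule.te_max_ms
        if te_max is not None:
            t2 = self.t2_ms_map()
            t2 = t2[np.isfinite(t2)]
            lines.append(f"T2 (ms) median:    {q(t2, 50):.1f}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<MonoExpDecayResults method={self.method} shape={self.fit.map.shape}>"
        )
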