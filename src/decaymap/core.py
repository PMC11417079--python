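"""Forward signal model, Rician noise process, SNR, and series preprocessing.

The signal model is a normalized mono-exponential decay,

    S(eta) = S0 * exp(-eta / T),

where ``eta`` is the dimensionless sampling dimension (echo time divided by
the maximum echo time in a T2-mapping acquisition), ``T`` the normalized time
constant (T2 / TE_max), and ``S0`` the signal at eta = 0.  Magnitude images
carry Rician rather than Gaussian noise: complex Gaussian noise of standard
deviation ``sigma`` in each channel followed by a magnitude operation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EchoSchedule",
    "ParameterMap",
    "ImageSeries",
    "NoiseSpec",
    "decay_signal",
    "add_rician_noise",
    "snr_db",
    "normalize_series",
    "preprocess_series",
]


@dataclass(frozen=True)
class EchoSchedule:
    """The normalized sampling dimension eta and its physical TE provenance.

    Parameters
    ----------
    eta : ndarray
        Strictly ascending, positive, with ``max(eta) == 1.0`` exactly.
    te_ms : ndarray, optional
        Physical echo times in milliseconds; must satisfy
        ``eta == te_ms / te_max_ms`` elementwise.
    te_max_ms : float, optional
        The maximum echo time in milliseconds.
    """

    eta: np.ndarray
    te_ms: np.ndarray | None = None
    te_max_ms: float | None = None

    def __post_init__(self) -> None:
        eta = np.asarray(self.eta, dtype=float)
        object.__setattr__(self, "eta", eta)
        if eta.ndim != 1 or eta.size < 1:
            raise ValueError("eta must be a 1-D vector with at least one point")
        if np.any(np.diff(eta) <= 0):
            raise ValueError("eta must be strictly ascending")
        if np.any(eta <= 0):
            raise ValueError("all eta must be positive")
        if eta[-1] != 1.0:
            raise ValueError(f"max(eta) must equal 1.0 exactly, got {eta[-1]!r}")
        if self.te_ms is not None:
            te = np.asarray(self.te_ms, dtype=float)
            object.__setattr__(self, "te_ms", te)
            if self.te_max_ms is None:
                object.__setattr__(self, "te_max_ms", float(te[-1]))
            if not np.allclose(eta, te / self.te_max_ms, rtol=1e-10, atol=0):
                raise ValueError("eta and te_ms/te_max_ms disagree")

    @property
    def n(self) -> int:
        """Number of sampling points (N in the SNR definition)."""
        return int(self.eta.size)

    @classmethod
    def from_te_ms(cls, te_ms) -> "EchoSchedule":
        """Build a schedule from physical echo times; eta = TE / TE_max."""
        te = np.asarray(te_ms, dtype=float)
        return cls(eta=te / te.max(), te_ms=te, te_max_ms=float(te.max()))

    @classmethod
    def default_synthetic(cls) -> "EchoSchedule":
        """The 10-echo synthesis grid eta = k/11, k = 2..11 (first echo absent)."""
        k = np.arange(2, 12, dtype=float)
        return cls(eta=k / 11.0)

    @classmethod
    def invivo_11echo(cls) -> "EchoSchedule":
        """Eleven echoes, TE = 13.2..145.2 ms in 13.2 ms steps (eta = k/11, k=1..11)."""
        te = 13.2 * np.arange(1, 12)
        return cls.from_te_ms(te)

    def drop_first(self) -> "EchoSchedule":
        """Schedule without its first point; max(eta) is unchanged (still 1.0)."""
        if self.n < 2:
            raise ValueError("cannot drop the only sampling point")
        te = self.te_ms[1:] if self.te_ms is not None else None
        return EchoSchedule(eta=self.eta[1:], te_ms=te, te_max_ms=self.te_max_ms)

    def same_grid(self, other: "EchoSchedule", rtol: float = 1e-8) -> bool:
        return self.n == other.n and bool(np.allclose(self.eta, other.eta, rtol=rtol))


@dataclass
class ParameterMap:
    """Per-pixel S0 and T maps (ground truth or estimate).

    ``sigma_rice`` is populated only by estimators that fit the noise level.
    """

    s0: np.ndarray
    t: np.ndarray
    sigma_rice: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.s0 = np.asarray(self.s0, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.s0.shape != self.t.shape:
            raise ValueError("s0 and t must have identical spatial dimensions")
        if self.sigma_rice is not None:
            self.sigma_rice = np.asarray(self.sigma_rice, dtype=float)
            if self.sigma_rice.shape != self.t.shape:
                raise ValueError("sigma_rice shape mismatch")

    @property
    def shape(self) -> tuple:
        return self.s0.shape

    @property
    def r(self) -> np.ndarray:
        """Decay rate R = 1/T."""
        with np.errstate(divide="ignore"):
            return 1.0 / self.t


@dataclass
class ImageSeries:
    """One slice's multi-echo magnitude stack (height x width x n_echo)."""

    data: np.ndarray
    schedule: EchoSchedule
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be height x width x n_echo")
        if self.data.shape[2] != self.schedule.n:
            raise ValueError(
                f"series has {self.data.shape[2]} echoes but schedule has {self.schedule.n}"
            )
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be nonnegative")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:2]


@dataclass(frozen=True)
class NoiseSpec:
    """Complex Gaussian channel noise: std ``sigma`` plus a reproducibility seed."""

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def decay_signal(s0, t, schedule: EchoSchedule) -> np.ndarray:
    """Evaluate S(eta) = S0 exp(-eta/T) on a schedule.

    Scalars or maps are accepted for ``s0`` and ``t``; the output gains a
    trailing echo axis of length ``schedule.n``.  Internally the rate
    R = 1/T is used, so T = 0 is rejected rather than mapped to zero signal.
    """
    s0 = np.asarray(s0, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("time constant t must be strictly positive")
    r = 1.0 / t
    return s0[..., None] * np.exp(-schedule.eta * r[..., None])


def add_rician_noise(series: ImageSeries, noise: NoiseSpec) -> ImageSeries:
    """Corrupt a magnitude series with Rician noise.

    Each pixel value m becomes ``|m + g1 + i*g2|`` with g1, g2 independent
    N(0, sigma^2) draws.  Deterministic given ``noise.seed``; sigma = 0 is the
    identity.
    """
    if noise.sigma < 0:
        raise ValueError("sigma must be >= 0")
    if noise.sigma == 0:
        return ImageSeries(series.data.copy(), series.schedule, series.normalized)
    rng = np.random.default_rng(noise.seed)
    g = rng.normal(0.0, noise.sigma, size=(2,) + series.data.shape)
    out = np.hypot(series.data + g[0], g[1])
    # magnitude noise moves the global max; the normalized flag no longer holds
    return ImageSeries(out, series.schedule, normalized=False)


def snr_db(s0, t, sigma, schedule: EchoSchedule) -> np.ndarray:
    """Per-pixel SNR in dB: 20 log10(||S(eta)||_2 / (sigma sqrt(N))).

    Pixels with ``s0 = 0`` give -inf (propagated as a sentinel; such pixels
    fall below every finite bin edge downstream).  ``sigma`` must be positive.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive (sigma = 0 has infinite SNR)")
    sig = decay_signal(s0, t, schedule)
    l2 = np.sqrt(np.sum(sig * sig, axis=-1))
    with np.errstate(divide="ignore"):
        return 20.0 * np.log10(l2 / (sigma * np.sqrt(schedule.n)))


def normalize_series(series: ImageSeries) -> ImageSeries:
    """Scale so the maximum over all three dimensions equals 1.0; idempotent."""
    m = float(series.data.max())
    if m <= 0:
        raise ValueError("cannot normalize an all-zero series")
    if m == 1.0:
        return ImageSeries(series.data, series.schedule, normalized=True)
    return ImageSeries(series.data / m, series.schedule, normalized=True)


def preprocess_series(
    series: ImageSeries, crop: int = 128, drop_first: bool = True
) -> ImageSeries:
    """Center-crop spatially and optionally discard the first echo.

    Mirrors the standard multi-echo preprocessing: crop to ``crop`` x ``crop``
    pixels and drop the first echo (stimulated-echo contamination).  Synthetic
    series are generated first-echo-free already, so ``drop_first=False`` makes
    the echo step a no-op.  Odd crop excess puts the extra pixel at the end
    (leading offset ``floor((dim - crop) / 2)``).
    """
    h, w, n = series.data.shape
    if h < crop or w < crop:
        raise ValueError(f"spatial dims {(h, w)} smaller than crop {crop}")
    if drop_first and n < 2:
        raise ValueError("need at least 2 echoes to discard the first")
    i0 = (h - crop) // 2
    j0 = (w - crop) // 2
    data = series.data[i0 : i0 + crop, j0 : j0 + crop, :]
    sched = series.schedule
    if drop_first:
        data = data[:, :, 1:]
        sched = sched.drop_first()
    return ImageSeries(data.copy(), sched, series.normalized)
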