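"""Physics-based synthetic relaxometry datasets with known ground truth.

Two corpora are supported:

* **corpus mode** — ground-truth S0 and T maps are grayscale images drawn from
  an image corpus (naturalistic photographs, or the built-in procedural
  corpus), giving spatially correlated parameter maps;
* **urand mode** — every pixel of S0 and T is drawn i.i.d. uniform over the
  configured ranges, removing all spatial correlation.

The contrast between the two isolates the contribution of learned spatial
priors when convolutional estimators are trained/evaluated on them.

Each record is built by evaluating the forward decay model on the ground-truth
maps and corrupting it with Rician noise whose channel std is drawn once per
series from ``sigma_range``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import (
    EchoSchedule,
    ImageSeries,
    NoiseSpec,
    ParameterMap,
    add_rician_noise,
    decay_signal,
)

__all__ = [
    "SynthConfig",
    "SynthRecord",
    "prepare_reference_image",
    "synthesize_series_pair",
    "build_synthetic_dataset",
    "procedural_corpus",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for a synthetic dataset.

    Defaults emulate the reference conditions: 128 x 128 maps, S0 in [0, 1],
    T in [0.045, 4], per-series channel noise sigma ~ Uniform[0.001, 0.1],
    10 echoes at eta = k/11 for k = 2..11.
    """

    n_series: int = 1000
    size: int = 128
    s0_range: tuple = (0.0, 1.0)
    t_range: tuple = (0.045, 4.0)
    sigma_range: tuple = (0.001, 0.1)
    schedule: EchoSchedule = field(default_factory=EchoSchedule.default_synthetic)
    mode: str = "urand"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_series < 1:
            raise ValueError("n_series must be >= 1")
        for name in ("s0_range", "t_range", "sigma_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be ordered (lo < hi)")
        if self.t_range[0] <= 0:
            raise ValueError("t_range lower bound must be > 0")
        if self.mode not in ("corpus", "urand"):
            raise ValueError("mode must be 'corpus' or 'urand'")


@dataclass
class SynthRecord:
    """A noisy series, its exact ground-truth maps, and the noise level used."""

    series: ImageSeries
    truth: ParameterMap
    sigma: float


def prepare_reference_image(
    image: np.ndarray, size: int, lo: float, hi: float
) -> np.ndarray:
    """Turn a grayscale/color image into a parameter map in [lo, hi].

    Color images are averaged over channels; images smaller than ``size`` are
    bicubically resized up before the center crop; the crop is min-max scaled
    linearly onto [lo, hi].  A constant-valued image has zero dynamic range and
    maps to the midpoint (lo + hi) / 2 with a warning.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale or H x W x C color")
    h, w = img.shape
    if min(h, w) < size:
        zoom = size / min(h, w)
        img = ndimage.zoom(img, zoom, order=3)
        h, w = img.shape
        if min(h, w) < size:  # guard against rounding down
            pad_h, pad_w = max(0, size - h), max(0, size - w)
            img = np.pad(img, ((0, pad_h), (0, pad_w)), mode="edge")
            h, w = img.shape
    i0, j0 = (h - size) // 2, (w - size) // 2
    img = img[i0 : i0 + size, j0 : j0 + size]
    mn, mx = float(img.min()), float(img.max())
    if mx == mn:
        warnings.warn("constant image has zero dynamic range; mapping to midpoint")
        return np.full((size, size), 0.5 * (lo + hi))
    return lo + (img - mn) * (hi - lo) / (mx - mn)


def synthesize_series_pair(
    s0_map: np.ndarray,
    t_map: np.ndarray,
    schedule: EchoSchedule,
    sigma: float,
    seed: int,
) -> SynthRecord:
    """Forward-simulate one noisy series from ground-truth maps."""
    s0_map = np.asarray(s0_map, dtype=float)
    t_map = np.asarray(t_map, dtype=float)
    if s0_map.shape != t_map.shape:
        raise ValueError("s0 and t maps must have the same shape")
    clean = ImageSeries(decay_signal(s0_map, t_map, schedule), schedule)
    noisy = add_rician_noise(clean, NoiseSpec(sigma=sigma, seed=seed))
    return SynthRecord(series=noisy, truth=ParameterMap(s0_map, t_map), sigma=sigma)


def build_synthetic_dataset(
    config: SynthConfig, corpus: Sequence[np.ndarray] | None = None
) -> list[SynthRecord]:
    """Build ``config.n_series`` records with per-series noise levels.

    In corpus mode two *distinct* corpus images are consumed per record (no
    image reused within the dataset), one for S0 and one for T.  In urand mode
    every pixel is drawn independently from the configured uniform ranges.
    """
    rng = np.random.default_rng(config.seed)
    if config.mode == "corpus":
        if corpus is None:
            raise ValueError("corpus mode requires an image corpus")
        needed = 2 * config.n_series
        if len(corpus) < needed:
            raise ValueError(
                f"corpus has {len(corpus)} images but {needed} are required "
                f"(2 per series, no reuse)"
            )
        order = rng.permutation(len(corpus))
    records: list[SynthRecord] = []
    for i in range(config.n_series):
        sigma = float(rng.uniform(*config.sigma_range))
        # independent per-series noise stream, reproducible from the dataset seed
        noise_seed = int(rng.integers(0, 2**31 - 1))
        if config.mode == "urand":
            shape = (config.size, config.size)
            s0 = rng.uniform(*config.s0_range, size=shape)
            t = rng.uniform(*config.t_range, size=shape)
        else:
            img_s0 = corpus[order[2 * i]]
            img_t = corpus[order[2 * i + 1]]
            s0 = prepare_reference_image(img_s0, config.size, *config.s0_range)
            t = prepare_reference_image(img_t, config.size, *config.t_range)
        records.append(
            synthesize_series_pair(s0, t, config.schedule, sigma, noise_seed)
        )
    return records


def _random_field(rng: np.random.Generator, size: int, scale: float) -> np.ndarray:
    """Gaussian random field: white noise smoothed at a given length scale."""
    return ndimage.gaussian_filter(rng.normal(size=(size, size)), sigma=scale)


def procedural_corpus(n: int, size: int = 128, seed: int = 0) -> list[np.ndarray]:
    """Generate ``n`` grayscale images in [0, 1] with naturalistic structure.

    Each image mixes Gaussian random fields at two length scales with a few
    overlaid constant-intensity ellipses and rectangles, giving the smooth
    gradients, textures and piecewise-constant regions that make corpus-mode
    parameter maps spatially correlated.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    images: list[np.ndarray] = []
    for _ in range(n):
        smooth = _random_field(rng, size, rng.uniform(size / 16, size / 6))
        texture = _random_field(rng, size, rng.uniform(1.5, 4.0))
        img = smooth / (np.abs(smooth).max() + 1e-12)
        img = img + 0.35 * texture / (np.abs(texture).max() + 1e-12)
        for _ in range(rng.integers(1, 4)):
            cy, cx = rng.uniform(0, size, size=2)
            ry, rx = rng.uniform(size / 16, size / 4, size=2)
            level = rng.uniform(-1, 1)
            if rng.random() < 0.5:
                mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
            else:
                mask = (np.abs(yy - cy) <= ry) & (np.abs(xx - cx) <= rx)
            img = np.where(mask, 0.6 * img + level, img)
        mn, mx = img.min(), img.max()
        images.append(np.clip((img - mn) / (mx - mn + 1e-12), 0.0, 1.0))
    return images
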