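"""Supervised training of the neural estimators on synthetic datasets.

Both networks are trained with a mean squared error loss against the
ground-truth (S0, T) maps using AdamW at learning rate 0.002.  The 1-D
network consumes single-pixel decay curves extracted from the image series;
the CNN consumes whole series as 10-channel images with 2-channel targets.
Records are split into train/validation subsets at the series level (80/20
by default); the best-validation-loss weights are restored at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core import EchoSchedule, ImageSeries, ParameterMap
from ..synth import SynthRecord
from .layers import Module, mse_loss
from .optim import AdamW

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "extract_pixel_curves",
    "train_model",
    "predict_map",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training recipe.

    Reference recipes: 5 epochs / batch 10,000 curves for the 1-D network;
    1000 epochs / batch 100 series for the CNN — both scale down freely.
    """

    epochs: int = 5
    batch_size: int = 10_000
    lr: float = 0.002
    weight_decay: float = 0.01
    val_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be > 0")
        if not 0.0 < self.val_frac < 1.0:
            raise ValueError("val_frac must be in (0, 1)")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    best_epoch: int = -1

    @property
    def best_val_loss(self) -> float:
        return min(self.val_loss) if self.val_loss else float("nan")


def _check_common_schedule(dataset: list[SynthRecord]) -> EchoSchedule:
    sched = dataset[0].series.schedule
    for rec in dataset[1:]:
        if not sched.same_grid(rec.series.schedule):
            raise ValueError("records have mismatching echo schedules")
    return sched


def extract_pixel_curves(dataset: list[SynthRecord]):
    """All single-pixel decay curves and their (S0, T) targets.

    Order is deterministic: record-major, then row-major within each map.
    An 800-series 128 x 128 dataset yields 13,107,200 curves.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    sched = _check_common_schedule(dataset)
    n = sched.n
    curves = np.concatenate([rec.series.data.reshape(-1, n) for rec in dataset])
    targets = np.concatenate(
        [
            np.stack([rec.truth.s0.reshape(-1), rec.truth.t.reshape(-1)], axis=1)
            for rec in dataset
        ]
    )
    return curves, targets


def _image_tensors(dataset: list[SynthRecord]):
    x = np.stack([rec.series.data.transpose(2, 0, 1) for rec in dataset])
    y = np.stack([np.stack([rec.truth.s0, rec.truth.t]) for rec in dataset])
    return x, y


def _epoch_pass(model, opt, x, y, batch, rng):
    order = rng.permutation(x.shape[0])
    losses = []
    for start in range(0, len(order), batch):
        idx = order[start : start + batch]
        model.zero_grad()
        pred = model(x[idx])
        loss, grad = mse_loss(pred, y[idx])
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged: loss = {loss}")
        model.backward(grad)
        opt.step()
        losses.append(loss)
    return float(np.mean(losses))


def _eval_loss(model, x, y, batch) -> float:
    total, count = 0.0, 0
    for start in range(0, x.shape[0], batch):
        pred = model(x[start : start + batch])
        d = pred - y[start : start + batch]
        total += float(np.sum(d * d))
        count += d.size
    return total / count


def train_model(
    model: Module, dataset: list[SynthRecord], config: TrainConfig
) -> TrainingHistory:
    """Train in place; restores best-validation weights and records history.

    The series-level split uses ``config.seed``; zero epochs returns the
    initial weights with an empty history.  The dataset's echo schedule is
    attached to the model so later predictions can detect grid mismatches.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    sched = _check_common_schedule(dataset)
    rng = np.random.default_rng(config.seed)
    n_val = max(1, int(round(config.val_frac * len(dataset))))
    if n_val >= len(dataset):
        raise ValueError("dataset too small for the requested validation split")
    order = rng.permutation(len(dataset))
    val_recs = [dataset[i] for i in order[:n_val]]
    train_recs = [dataset[i] for i in order[n_val:]]

    if getattr(model, "input_kind", "curve") == "curve":
        x_tr, y_tr = extract_pixel_curves(train_recs)
        x_va, y_va = extract_pixel_curves(val_recs)
    else:
        factor = model.spec.down_factor
        h, w = dataset[0].series.spatial_shape
        if h % factor or w % factor:
            raise ValueError(f"spatial dims must be divisible by {factor}")
        x_tr, y_tr = _image_tensors(train_recs)
        x_va, y_va = _image_tensors(val_recs)

    model.schedule = sched
    history = TrainingHistory()
    if config.epochs == 0:
        return history

    opt = AdamW(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    best_state = model.state()
    best_val = np.inf
    eval_batch = max(config.batch_size, 1)
    for epoch in range(config.epochs):
        model.train()
        tr = _epoch_pass(model, opt, x_tr, y_tr, config.batch_size, rng)
        model.eval()
        va = _eval_loss(model, x_va, y_va, eval_batch)
        history.train_loss.append(tr)
        history.val_loss.append(va)
        if va < best_val:
            best_val = va
            best_state = model.state()
            history.best_epoch = epoch
    model.load_state(best_state)
    model.eval()
    return history


def predict_map(model: Module, series: ImageSeries) -> ParameterMap:
    """Apply a trained estimator to a series, returning the (S0, T) maps.

    The series' echo schedule must match the grid the model was trained on;
    mismatches raise rather than silently interpolating.  No clipping is
    applied to the outputs.
    """
    sched = getattr(model, "schedule", None)
    if sched is None:
        raise ValueError("model has not been trained (no schedule attached)")
    if not sched.same_grid(series.schedule):
        raise ValueError("series echo schedule does not match the training grid")
    model.eval()
    h, w, n = series.data.shape
    if getattr(model, "input_kind", "curve") == "curve":
        out = model(series.data.reshape(-1, n))
        return ParameterMap(out[:, 0].reshape(h, w), out[:, 1].reshape(h, w))
    factor = model.spec.down_factor
    if h % factor or w % factor:
        raise ValueError(f"spatial dims must be divisible by {factor}")
    out = model(series.data.transpose(2, 0, 1)[None])
    return ParameterMap(out[0, 0], out[0, 1])
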