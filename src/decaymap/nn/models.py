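"""The two neural estimator architectures.

``build_nn1d`` constructs the per-pixel fully connected network: a 10-vector
of echo magnitudes in, (S0, T) out, five 64-wide weight layers between input
and output with ReLU activations — 17,474 trainable parameters.

``build_cnn`` constructs a residual U-Net for whole-series parameter-map
regression: 10 input channels (one per echo), 2 output channels (S0, T),
encoder/decoder widths (128, 128, 256, 512) with three stride-2 stages at the
reference size, two-convolution residual units on the way down, concatenating
skips, transposed-convolution upsampling, batch normalization and PReLU
activations, and a linear head (regression targets are not bounded).  The
reference configuration has 6,950,457 trainable parameters (quoted as 6.9 M).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import (
    ConvTranspose2d,
    Dense,
    Module,
    PReLU,
    ReLU,
    ResidualUnit,
    Sequential,
    SkipConnection,
)

__all__ = [
    "NN1DSpec",
    "CNNSpec",
    "build_nn1d",
    "build_cnn",
    "count_trainable_params",
]


@dataclass(frozen=True)
class NN1DSpec:
    """Layer stack 10 -> 64 -> 64 x4 -> 2 with ReLU between weight layers."""

    n_in: int = 10
    width: int = 64
    n_hidden: int = 5  # number of consecutive width-wide weight layers
    n_out: int = 2


@dataclass(frozen=True)
class CNNSpec:
    """U-Net configuration; len(channels) - 1 stride-2 resolution stages."""

    in_channels: int = 10
    out_channels: int = 2
    channels: tuple = (128, 128, 256, 512)
    strides: tuple = (2, 2, 2)
    num_res_units: int = 2

    def __post_init__(self) -> None:
        if len(self.channels) != len(self.strides) + 1:
            raise ValueError("need len(channels) == len(strides) + 1")
        if len(self.channels) < 2:
            raise ValueError("need at least 2 channel widths")

    @classmethod
    def scaled_down(cls) -> "CNNSpec":
        """Narrow preset for CPU-only end-to-end training runs."""
        return cls(channels=(16, 16, 32, 64), strides=(2, 2, 2))

    @property
    def down_factor(self) -> int:
        return int(np.prod(self.strides))


def build_nn1d(spec: NN1DSpec = NN1DSpec(), seed: int = 0) -> Sequential:
    """Per-pixel decay-curve regressor; deterministic init given ``seed``."""
    rng = np.random.default_rng(seed)
    layers: list[Module] = [Dense(spec.n_in, spec.width, rng), ReLU()]
    for _ in range(spec.n_hidden - 1):
        layers += [Dense(spec.width, spec.width, rng), ReLU()]
    layers.append(Dense(spec.width, spec.n_out, rng))
    model = Sequential(layers)
    model.input_kind = "curve"
    model.spec = spec
    return model


class _UpLayer(Module):
    """Transposed-conv upsampling followed by a single-subunit residual unit."""

    def __init__(self, c_in, c_out, rng, stride, is_top):
        super().__init__()
        from .layers import BatchNorm2d

        self.up = ConvTranspose2d(c_in, c_out, rng, stride=stride)
        self.norm = BatchNorm2d(c_out)
        self.act = PReLU()
        self.ru = ResidualUnit(
            c_out, c_out, rng, stride=1, subunits=1, last_conv_only=is_top
        )

    def forward(self, x):
        return self.ru(self.act(self.norm(self.up(x))))

    def backward(self, grad):
        grad = self.ru.backward(grad)
        grad = self.act.backward(grad)
        grad = self.norm.backward(grad)
        return self.up.backward(grad)


def build_cnn(spec: CNNSpec = CNNSpec(), seed: int = 0) -> Sequential:
    """Residual U-Net built recursively: down, deeper block in a skip, up."""
    rng = np.random.default_rng(seed)

    def make_block(c_in, c_out, channels, strides, is_top):
        c, s = channels[0], strides[0]
        if len(channels) > 2:
            sub = make_block(c, c, channels[1:], strides[1:], False)
            upc = c * 2
        else:
            sub = ResidualUnit(c, channels[1], rng, stride=1, subunits=spec.num_res_units)
            upc = c + channels[1]
        down = ResidualUnit(c_in, c, rng, stride=s, subunits=spec.num_res_units)
        up = _UpLayer(upc, c_out, rng, stride=s, is_top=is_top)
        return Sequential([down, SkipConnection(sub), up])

    model = make_block(
        spec.in_channels, spec.out_channels, spec.channels, spec.strides, True
    )
    model.input_kind = "image"
    model.spec = spec
    return model


def count_trainable_params(model: Module) -> int:
    """Total size of all trainable parameter tensors."""
    return int(sum(p.value.size for p in model.parameters() if p.trainable))
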