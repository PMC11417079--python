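"""Minimal NumPy neural-network layers with explicit backpropagation.

Implements exactly the building blocks the two estimator architectures need:
dense layers, 2-D (transposed) convolutions via im2col/col2im, batch
normalization, (P)ReLU, sequential containers, concatenating skip
connections, and residual units.  Data layout is channels-first,
``(batch, channels, height, width)``.

Every layer caches what its backward pass needs during ``forward`` and
returns the input gradient from ``backward``; parameters accumulate their
gradients in ``Parameter.grad``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Module",
    "Dense",
    "ReLU",
    "PReLU",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "Sequential",
    "SkipConnection",
    "ResidualUnit",
    "mse_loss",
]


class Parameter:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad", "trainable")

    def __init__(self, value: np.ndarray, trainable: bool = True):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable


class Module:
    """Base class: parameter discovery, train/eval mode, call protocol."""

    def __init__(self) -> None:
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def parameters(self) -> list[Parameter]:
        """All parameters in deterministic attribute order."""
        params: list[Parameter] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for _, v in sorted(vars(obj).items()):
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return params

    def modules(self):
        yield self
        for _, v in sorted(vars(self).items()):
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for m in v:
                    if isinstance(m, Module):
                        yield from m.modules()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def train(self, flag: bool = True) -> "Module":
        for m in self.modules():
            m.training = flag
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def load_state(self, state) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state length does not match parameter count")
        for p, v in zip(params, state):
            if p.value.shape != np.shape(v):
                raise ValueError("state shape mismatch")
            p.value[...] = v


def _uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Dense(Module):
    """Affine layer y = x W^T + b on (batch, features) inputs."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = Parameter(_uniform_init(rng, (n_out, n_in), n_in))
        self.b = Parameter(_uniform_init(rng, (n_out,), n_in))

    def forward(self, x):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad):
        self.w.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class PReLU(Module):
    """Parametric ReLU with a single shared slope (initialized 0.25)."""

    def __init__(self, init: float = 0.25):
        super().__init__()
        self.a = Parameter(np.array(init))

    def forward(self, x):
        self._x = x
        self._mask = x > 0
        return np.where(self._mask, x, self.a.value * x)

    def backward(self, grad):
        self.a.grad += np.sum(np.where(self._mask, 0.0, grad * self._x))
        return np.where(self._mask, grad, self.a.value * grad)


# ---------------------------------------------------------------------------
# im2col / col2im
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int, s: int, p: int):
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    ho = (h + 2 * p - k) // s + 1
    wo = (w + 2 * p - k) // s + 1
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * k * k, ho * wo)
    return cols, (ho, wo)


def _col2im(cols, b, c, grid, k, s, p, h, w):
    """Adjoint of _im2col: scatter-add columns back onto the image."""
    gh, gw = grid
    xp = np.zeros((b, c, h + 2 * p, w + 2 * p))
    cols6 = cols.reshape(b, c, k, k, gh, gw)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + s * gh : s, j : j + s * gw : s] += cols6[:, :, i, j]
    return xp[:, :, p : p + h, p : p + w]


class Conv2d(Module):
    def __init__(self, c_in, c_out, rng, k: int = 3, stride: int = 1, pad: int = 1):
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        fan_in = c_in * k * k
        self.w = Parameter(_uniform_init(rng, (c_out, fan_in), fan_in))
        self.b = Parameter(_uniform_init(rng, (c_out,), fan_in))

    def forward(self, x):
        self._xshape = x.shape
        cols, grid = _im2col(x, self.k, self.stride, self.pad)
        self._cols, self._grid = cols, grid
        y = np.matmul(self.w.value, cols) + self.b.value[:, None]
        b = x.shape[0]
        return y.reshape(b, self.c_out, *grid)

    def backward(self, grad):
        b, _, gh, gw = grad.shape
        gf = grad.reshape(b, self.c_out, gh * gw)
        self.w.grad += np.einsum("bol,bkl->ok", gf, self._cols)
        self.b.grad += gf.sum(axis=(0, 2))
        dcols = np.matmul(self.w.value.T, gf)
        _, _, h, w = self._xshape
        return _col2im(
            dcols, b, self.c_in, self._grid, self.k, self.stride, self.pad, h, w
        )


class ConvTranspose2d(Module):
    """Strided transposed convolution (output_padding = stride - 1)."""

    def __init__(self, c_in, c_out, rng, k: int = 3, stride: int = 2, pad: int = 1):
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        self.out_pad = stride - 1
        fan_in = c_out * k * k
        self.w = Parameter(_uniform_init(rng, (c_in, fan_in), fan_in))
        self.b = Parameter(_uniform_init(rng, (c_out,), fan_in))

    def _out_size(self, n: int) -> int:
        return (n - 1) * self.stride - 2 * self.pad + self.k + self.out_pad

    def forward(self, x):
        b, _, h, w = x.shape
        self._xf = x.reshape(b, self.c_in, h * w)
        self._grid = (h, w)
        ho, wo = self._out_size(h), self._out_size(w)
        self._oshape = (ho, wo)
        cols = np.matmul(self.w.value.T, self._xf)
        y = _col2im(cols, b, self.c_out, (h, w), self.k, self.stride, self.pad, ho, wo)
        return y + self.b.value[None, :, None, None]

    def backward(self, grad):
        b = grad.shape[0]
        self.b.grad += grad.sum(axis=(0, 2, 3))
        gcols, grid = _im2col(grad, self.k, self.stride, self.pad)
        assert grid == self._grid
        self.w.grad += np.einsum("bcl,bkl->ck", self._xf, gcols)
        dxf = np.matmul(self.w.value, gcols)
        h, w = self._grid
        return dxf.reshape(b, self.c_in, h, w)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, x):
        axes = (0, 2, 3)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = x.shape[0] * x.shape[2] * x.shape[3]
            self.running_mean += self.momentum * (mean - self.running_mean)
            unbiased = var * m / max(m - 1, 1)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[:, None, None]) / self._std[:, None, None]
        return (
            self.gamma.value[:, None, None] * self._xhat
            + self.beta.value[:, None, None]
        )

    def backward(self, grad):
        axes = (0, 2, 3)
        self.gamma.grad += np.sum(grad * self._xhat, axis=axes)
        self.beta.grad += np.sum(grad, axis=axes)
        g = grad * self.gamma.value[:, None, None]
        if not self.training:
            return g / self._std[:, None, None]
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        mean_g = g.mean(axis=axes)
        mean_gx = (g * self._xhat).mean(axis=axes)
        return (
            g
            - mean_g[:, None, None]
            - self._xhat * mean_gx[:, None, None]
        ) / self._std[:, None, None]


class Sequential(Module):
    def __init__(self, layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class SkipConnection(Module):
    """Concatenate a submodule's output with its input along channels."""

    def __init__(self, submodule: Module):
        super().__init__()
        self.submodule = submodule

    def forward(self, x):
        self._c_in = x.shape[1]
        y = self.submodule(x)
        return np.concatenate([x, y], axis=1)

    def backward(self, grad):
        gx = grad[:, : self._c_in]
        gy = grad[:, self._c_in :]
        return gx + self.submodule.backward(gy)


class _ConvUnit(Module):
    """Convolution optionally followed by batch norm and PReLU."""

    def __init__(self, c_in, c_out, rng, stride=1, conv_only=False):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, rng, stride=stride)
        self.norm = None if conv_only else BatchNorm2d(c_out)
        self.act = None if conv_only else PReLU()

    def forward(self, x):
        y = self.conv(x)
        if self.norm is not None:
            y = self.norm(y)
            y = self.act(y)
        return y

    def backward(self, grad):
        if self.norm is not None:
            grad = self.act.backward(grad)
            grad = self.norm.backward(grad)
        return self.conv.backward(grad)


class ResidualUnit(Module):
    """Stack of conv subunits with a parallel residual path.

    The first subunit carries the stride and the channel change.  The
    residual path is the identity when shape-preserving, a strided k x k
    convolution when downsampling, or a 1 x 1 convolution when only the
    channel count changes.
    """

    def __init__(
        self, c_in, c_out, rng, stride=1, subunits=2, last_conv_only=False
    ):
        super().__init__()
        units = []
        sc, ss = c_in, stride
        for i in range(max(subunits, 1)):
            conv_only = last_conv_only and i == max(subunits, 1) - 1
            units.append(_ConvUnit(sc, c_out, rng, stride=ss, conv_only=conv_only))
            sc, ss = c_out, 1
        self.path = Sequential(units)
        if stride != 1 or c_in != c_out:
            rk = 3 if stride != 1 else 1
            self.residual = Conv2d(c_in, c_out, rng, k=rk, stride=stride, pad=rk // 2)
        else:
            self.residual = None

    def forward(self, x):
        res = x if self.residual is None else self.residual(x)
        return self.path(x) + res

    def backward(self, grad):
        gx = self.path.backward(grad)
        if self.residual is None:
            return gx + grad
        return gx + self.residual.backward(grad)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    return loss, 2.0 * diff / diff.size
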