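"""Minimal neural-network core for the GAN and the diagnosis classifier.

All layers operate on float32 numpy arrays with explicit, manually derived
backward passes (verified against numerical gradients in the test suite).
Convolutions decompose into one small GEMM per kernel offset over strided
slices of the padded input; the input gradient accumulates the transposed
products back into the padded grid, so no scatter-add indexing is needed.

Conventions
-----------
* 4-D activations are ``(N, C, H, W)``; for EEG frames H indexes electrodes
  and W discrete sample times.
* ``forward(x, train=...)`` caches whatever the matching ``backward`` needs;
  a layer therefore holds the state of exactly one pending forward pass.
* Stochastic layers (dropout, Gaussian noise) draw from a ``numpy.random.
  Generator`` installed via :meth:`Layer.seed`; with ``train=False`` they are
  the identity.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base class: a differentiable map with optional parameters."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def seed(self, rng: np.random.Generator) -> None:
        """Install the random generator used in training mode (no-op here)."""


def _same_geometry(n: int, k: int, s: int) -> tuple[int, int, int]:
    """Output size and asymmetric padding for 'same' convolution."""
    out = -(-n // s)
    pad = max((out - 1) * s + k - n, 0)
    return out, pad // 2, pad - pad // 2


class Conv2D(Layer):
    """2-D convolution with 'same' padding and arbitrary stride.

    Implemented as a sum over kernel offsets of strided slices multiplied by
    (out_ch, in_ch) weight matrices — one small GEMM per offset — which on
    the frame sizes used here is substantially faster than an im2col
    materialization.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: tuple[int, int] = (3, 5),
        stride: tuple[int, int] = (1, 1),
        *,
        rng: np.random.Generator | None = None,
        weight_scale: float | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        kh, kw = kernel
        fan_in = in_ch * kh * kw
        scale = weight_scale if weight_scale is not None else np.sqrt(2.0 / fan_in)
        self.W = (rng.standard_normal((out_ch, in_ch, kh, kw)) * scale).astype(DTYPE)
        self.b = np.zeros(out_ch, dtype=DTYPE)
        self.stride = stride
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        o, c, kh, kw = self.W.shape
        sh, sw = self.stride
        n, _, h, w = x.shape
        oh, pt, pb = _same_geometry(h, kh, sh)
        ow, pl, pr = _same_geometry(w, kw, sw)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        out = np.zeros((n, o, oh * ow), dtype=DTYPE)
        slices: list[np.ndarray] | None = [] if train else None
        for u in range(kh):
            for v in range(kw):
                sl = np.ascontiguousarray(
                    xp[:, :, u : u + (oh - 1) * sh + 1 : sh,
                       v : v + (ow - 1) * sw + 1 : sw]
                ).reshape(n, c, oh * ow)
                out += np.matmul(self.W[:, :, u, v], sl)
                if slices is not None:
                    slices.append(sl)
        out += self.b[None, :, None]
        self._cache = (slices, x.shape, (pt, pl), (oh, ow))
        return out.reshape(n, o, oh, ow)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        slices, xshape, (pt, pl), (oh, ow) = self._cache
        if slices is None:
            raise RuntimeError("backward requires a forward pass with train=True")
        n, c, h, w = xshape
        o, _, kh, kw = self.W.shape
        sh, sw = self.stride
        dr = dout.reshape(n, o, oh * ow)
        self.grads[1][...] = dr.sum(axis=(0, 2))
        # padded-input gradient, accumulated per kernel offset
        ph = _same_geometry(h, kh, sh)
        pw = _same_geometry(w, kw, sw)
        dxp = np.zeros((n, c, h + ph[1] + ph[2], w + pw[1] + pw[2]), dtype=DTYPE)
        k = 0
        for u in range(kh):
            for v in range(kw):
                sl = slices[k]
                k += 1
                self.grads[0][:, :, u, v] = np.tensordot(
                    dr, sl, axes=([0, 2], [0, 2])
                )
                dsl = np.matmul(self.W[:, :, u, v].T, dr).reshape(n, c, oh, ow)
                dxp[:, :, u : u + (oh - 1) * sh + 1 : sh,
                    v : v + (ow - 1) * sw + 1 : sw] += dsl
        return dxp[:, :, pt : pt + h, pl : pl + w]


class UpsampleConv2D(Layer):
    """Transposed-convolution stage: doubles the time axis then convolves.

    Realized as zero-interleaving along W followed by a 'same' Conv2D; the
    composition is the adjoint of a stride-(1,2) convolution and is what the
    generator uses to upsample 4 times by a factor of 2.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel=(3, 5), *, rng=None,
                 weight_scale: float | None = None) -> None:
        super().__init__()
        self.conv = Conv2D(in_ch, out_ch, kernel, (1, 1), rng=rng,
                           weight_scale=weight_scale)
        self.params = self.conv.params
        self.grads = self.conv.grads

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        up = np.zeros((n, c, h, 2 * w), dtype=DTYPE)
        up[:, :, :, ::2] = x
        return self.conv.forward(up, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dup = self.conv.backward(dout)
        return dup[:, :, :, ::2]


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, *, rng=None,
                 weight_scale: float | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = weight_scale if weight_scale is not None else np.sqrt(2.0 / in_dim)
        self.W = (rng.standard_normal((in_dim, out_dim)) * scale).astype(DTYPE)
        self.b = np.zeros(out_dim, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W) with running stats."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean[...] = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var[...] = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(DTYPE)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std, train)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std, train = self._cache
        self.grads[0][...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads[1][...] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        if not train:
            return dxhat / std[None, :, None, None]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        mean_d = dxhat.mean(axis=(0, 2, 3))[None, :, None, None]
        mean_dx = (dxhat * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        return (dxhat - mean_d - xhat * mean_dx) / std[None, :, None, None]


class MaxPool2d(Layer):
    """Non-overlapping max pooling; trailing rows/columns are dropped."""

    def __init__(self, pool: tuple[int, int]) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        ph, pw = self.pool
        n, c, h, w = x.shape
        oh, ow = h // ph, w // pw
        xc = x[:, :, : oh * ph, : ow * pw]
        win = xc.reshape(n, c, oh, ph, ow, pw).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(n, c, oh, ow, ph * pw)
        self._argmax = win.argmax(axis=-1)
        self._xshape = x.shape
        return win.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        ph, pw = self.pool
        n, c, h, w = self._xshape
        oh, ow = h // ph, w // pw
        dwin = np.zeros((n, c, oh, ow, ph * pw), dtype=DTYPE)
        np.put_along_axis(dwin, self._argmax[..., None], dout[..., None], axis=-1)
        dxc = dwin.reshape(n, c, oh, ow, ph, pw).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros((n, c, h, w), dtype=DTYPE)
        dx[:, :, : oh * ph, : ow * pw] = dxc.reshape(n, c, oh * ph, ow * pw)
        return dx


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x, train=False):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class ReLU(LeakyReLU):
    def __init__(self) -> None:
        super().__init__(slope=0.0)


class Tanh(Layer):
    def forward(self, x, train=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y**2)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class Dropout(Layer):
    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def seed(self, rng: np.random.Generator) -> None:
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate).astype(DTYPE) / (
            1.0 - self.rate
        )
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class GaussianNoise(Layer):
    """Adds N(0, std^2) noise in training mode; identity at inference."""

    def __init__(self, std: float) -> None:
        super().__init__()
        self.std = std
        self.rng = np.random.default_rng(0)

    def seed(self, rng: np.random.Generator) -> None:
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.std == 0.0:
            return x
        return x + self.std * self.rng.standard_normal(x.shape).astype(DTYPE)

    def backward(self, dout):
        return dout


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]) -> None:
        super().__init__()
        self.shape = shape

    def forward(self, x, train=False):
        self._in = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dout):
        return dout.reshape(self._in)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._in = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    @property
    def all_params(self) -> list[np.ndarray]:
        return [p for lay in self.layers for p in lay.params]

    @property
    def all_grads(self) -> list[np.ndarray]:
        return [g for lay in self.layers for g in lay.grads]

    def seed_stochastic(self, rng: np.random.Generator) -> None:
        for lay in self.layers:
            lay.seed(rng)

    def forward(self, x, train=False):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, dout):
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout


class Adam:
    """Adam optimizer over a fixed list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1: float,
                 beta2: float, eps: float) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def clip_params_(params: list[np.ndarray], clip_value: float) -> None:
    """Clamp every array in ``params`` to [-clip_value, clip_value] in place."""
    for p in params:
        np.clip(p, -clip_value, clip_value, out=p)
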