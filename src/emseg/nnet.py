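"""Minimal CPU neural-network engine (NumPy, float32).

Provides exactly the building blocks the segmentation networks here need:
2-D/3-D "same" convolutions (im2col matmul with explicit backprop), ReLU,
2x2 max-pooling, nearest-neighbour upsampling, residual/highway/dense
composition, and Adam.  Each layer instance is used once per forward pass and
caches what its backward pass needs; a model is trained by alternating
``forward`` / ``backward`` calls followed by an optimizer step.

Determinism: all parameter initialisation draws from a caller-supplied
``numpy.random.Generator``; the forward/backward math is pure NumPy and
reproducible bit-for-bit on a fixed BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=F32)
        self.grad = np.zeros_like(self.data)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = 1) -> np.ndarray:
    m = x.max(axis=axis, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=axis, keepdims=True)


class Module:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class _ConvNd(Module):
    """Same-size convolution with zero padding, kernel size 1 or 3."""

    def __init__(self, ndim: int, cin: int, cout: int, k: int, rng: np.random.Generator):
        if k not in (1, 3):
            raise ValueError("kernel size must be 1 or 3")
        self.ndim = ndim
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k**ndim
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, cout)))
        self.b = Param(np.zeros(cout))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        nd = self.ndim
        spatial = x.shape[2:]
        if p:
            pad = ((0, 0), (0, 0)) + ((p, p),) * nd
            xp = np.pad(x, pad)
        else:
            xp = x
        win = sliding_window_view(xp, (k,) * nd, axis=tuple(range(2, 2 + nd)))
        # win: (N, C, *spatial, *k) → (N, *spatial, C, *k)
        perm = (0,) + tuple(range(2, 2 + nd)) + (1,) + tuple(range(2 + nd, 2 + 2 * nd))
        cols = np.ascontiguousarray(win.transpose(perm), dtype=F32).reshape(
            -1, self.cin * k**nd
        )
        out = cols @ self.W.data + self.b.data
        out = out.reshape(x.shape[0], *spatial, self.cout)
        out = np.ascontiguousarray(np.moveaxis(out, -1, 1))
        self._cache = (cols, x.shape)
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        k, p, nd = self.k, self.k // 2, self.ndim
        n = xshape[0]
        spatial = xshape[2:]
        gyf = np.ascontiguousarray(np.moveaxis(gy, 1, -1), dtype=F32).reshape(
            -1, self.cout
        )
        self.W.grad += cols.T @ gyf
        self.b.grad += gyf.sum(axis=0)
        gcols = (gyf @ self.W.data.T).reshape(
            (n,) + spatial + (self.cin,) + (k,) * nd
        )
        # route each kernel tap back into the (zero-)padded input grad
        perm = (0, 1 + nd) + tuple(range(1, 1 + nd)) + tuple(range(2 + nd, 2 + 2 * nd))
        gcols = gcols.transpose(perm)  # (N, C, *spatial, *k)
        padded = tuple(s + 2 * p for s in spatial)
        gpad = np.zeros((n, self.cin) + padded, dtype=F32)
        for taps in np.ndindex(*(k,) * nd):
            sl = (slice(None), slice(None)) + tuple(
                slice(t, t + s) for t, s in zip(taps, spatial)
            )
            gpad[sl] += gcols[(Ellipsis,) + taps]
        if p:
            core = (slice(None), slice(None)) + (slice(p, -p),) * nd
            return np.ascontiguousarray(gpad[core])
        return gpad


class Conv2d(_ConvNd):
    def __init__(self, cin, cout, k, rng):
        super().__init__(2, cin, cout, k, rng)


class Conv3d(_ConvNd):
    def __init__(self, cin, cout, k, rng):
        super().__init__(3, cin, cout, k, rng)


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, gy):
        return np.where(self._mask, gy, 0)


class MaxPool2d(Module):
    """2x2 max pooling; spatial dims must be even."""

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        n, c, h, w = self._shape
        g = np.zeros((n, c, h // 2, w // 2, 4), dtype=F32)
        np.put_along_axis(g, self._idx[..., None], gy[..., None], axis=-1)
        g = g.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(g).reshape(n, c, h, w)


class Upsample2d(Module):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy):
        n, c, h, w = gy.shape
        return gy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Module):
    def __init__(self, layers: list[Module]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l(x)
        return x

    def backward(self, gy):
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy


class Residual(Module):
    """y = x + inner(x); the identity skip of a pre-activation residual unit."""

    def __init__(self, inner: Module):
        self.inner = inner

    def params(self):
        return self.inner.params()

    def forward(self, x):
        return x + self.inner(x)

    def backward(self, gy):
        return gy + self.inner.backward(gy)


class Highway2d(Module):
    """Gated unit: y = t*h + (1-t)*x with h = relu(conv_h(x)), t = sigmoid(conv_t(x))."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv_h = Conv2d(channels, channels, 3, rng)
        self.conv_t = Conv2d(channels, channels, 3, rng)
        # bias the transform gate towards carry at init, the usual highway trick
        self.conv_t.b.data[...] = -1.0

    def params(self):
        return self.conv_h.params() + self.conv_t.params()

    def forward(self, x):
        hpre = self.conv_h(x)
        self._hmask = hpre > 0
        h = np.where(self._hmask, hpre, 0)
        t = sigmoid(self.conv_t(x))
        self._x, self._h, self._t = x, h, t
        return t * h + (1.0 - t) * x

    def backward(self, gy):
        x, h, t = self._x, self._h, self._t
        gx = gy * (1.0 - t)
        gh = np.where(self._hmask, gy * t, 0)
        gt = gy * (h - x) * t * (1.0 - t)
        gx += self.conv_h.backward(gh)
        gx += self.conv_t.backward(gt)
        return gx


class DenseTrunk2d(Module):
    """Densely connected stack: layer i sees the concat of all earlier maps."""

    def __init__(self, channels: int, n_layers: int, growth: int, rng):
        self.growth = growth
        self.convs = []
        cin = channels
        for _ in range(n_layers):
            self.convs.append(Conv2d(cin, growth, 3, rng))
            cin += growth
        self.out_channels = cin
        self.relus: list[ReLU] = []

    def params(self):
        return [p for c in self.convs for p in c.params()]

    def forward(self, x):
        feats = [x]
        self.relus = []
        for conv in self.convs:
            r = ReLU()
            self.relus.append(r)
            feats.append(r(conv(np.concatenate(feats, axis=1))))
        self._widths = [f.shape[1] for f in feats]
        return np.concatenate(feats, axis=1)

    def backward(self, gy):
        # split the output grad back into per-feature-map grads
        splits = np.cumsum(self._widths)[:-1]
        gfeats = list(np.split(gy, splits, axis=1))
        for i in range(len(self.convs) - 1, -1, -1):
            gcat = self.convs[i].backward(self.relus[i].backward(gfeats[i + 1]))
            w = np.cumsum(self._widths[: i + 1])[:-1]
            for j, g in enumerate(np.split(gcat, w, axis=1)):
                gfeats[j] = gfeats[j] + g
        return gfeats[0]


class UNet2d(Module):
    """Contracting/expansive paths with skip connections.

    ``levels`` pooling steps; the downsampling factor is ``2**levels`` and
    input spatial dims must be divisible by it.
    """

    def __init__(self, in_ch: int, out_ch: int, base: int, levels: int, rng):
        self.levels = levels
        ch = [min(base * 2**i, base * 8) for i in range(levels + 1)]
        self.enc = [
            Sequential([Conv2d(in_ch if i == 0 else ch[i - 1], ch[i], 3, rng), ReLU()])
            for i in range(levels)
        ]
        self.pools = [MaxPool2d() for _ in range(levels)]
        self.bottleneck = Sequential([Conv2d(ch[levels - 1], ch[levels], 3, rng), ReLU()])
        self.ups = [Upsample2d() for _ in range(levels)]
        self.dec = [
            Sequential([Conv2d(ch[i + 1] + ch[i], ch[i], 3, rng), ReLU()])
            for i in range(levels)
        ]
        self.head = Conv2d(ch[0], out_ch, 1, rng)

    def params(self):
        ps = []
        for m in self.enc + [self.bottleneck] + self.dec + [self.head]:
            ps += m.params()
        return ps

    def forward(self, x):
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc(x)
            skips.append(x)
            x = pool(x)
        x = self.bottleneck(x)
        self._skip_ch = [s.shape[1] for s in skips]
        for i in range(self.levels - 1, -1, -1):
            x = self.ups[i](x)
            x = np.concatenate([skips[i], x], axis=1)
            x = self.dec[i](x)
        return self.head(x)

    def backward(self, gy):
        gy = self.head.backward(gy)
        gskips = [None] * self.levels
        for i in range(self.levels):
            gy = self.dec[i].backward(gy)
            gskips[i] = gy[:, : self._skip_ch[i]]
            gy = self.ups[i].backward(gy[:, self._skip_ch[i] :])
        gy = self.bottleneck.backward(gy)
        for i in range(self.levels - 1, -1, -1):
            gy = self.pools[i].backward(gy)
            gy = self.enc[i].backward(gy + gskips[i])
        return gy


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Param], lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0


def get_weights(model: Module) -> list[np.ndarray]:
    return [p.data.copy() for p in model.params()]


def set_weights(model: Module, weights: list[np.ndarray]) -> None:
    params = model.params()
    if len(params) != len(weights):
        raise ValueError("weight list does not match model parameters")
    for p, w in zip(params, weights):
        if p.data.shape != w.shape:
            raise ValueError(f"shape mismatch: {p.data.shape} vs {w.shape}")
        p.data[...] = w
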