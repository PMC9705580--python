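"""Minimal CPU neural-network layers with hand-written backward passes.

Kept deliberately small: only the layers the two networks in this package
need, implemented on numpy arrays with explicit ``forward``/``backward``
methods. Every layer caches what its backward pass needs during ``forward``
and is therefore single-use per step (call forward, then backward, in that
order). Gradients accumulate into ``Parameter.grad`` so that several
backward passes between optimizer steps realize gradient accumulation.

Array conventions:
  2-D layers: ``(N, C, H, W)``
  1-D layers: ``(C, L)`` (one artery per forward pass, no batch axis)
  dense layers: ``(..., features)``
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    @property
    def dtype(self):
        return self.value.dtype


class Module:
    """Base class: parameter collection plus train/eval mode flag."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for attr in vars(self).values():
            if isinstance(attr, Parameter):
                params.append(attr)
            elif isinstance(attr, Module):
                params.extend(attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)}")
        for p, v in zip(params, state):
            if p.value.shape != v.shape:
                raise ValueError(f"shape mismatch {p.value.shape} vs {v.shape}")
            p.value[...] = v


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


# ---------------------------------------------------------------------------
# convolutions


class Conv2d(Module):
    """3x3-style 2-D convolution, stride 1, zero 'same' padding."""

    def __init__(self, cin: int, cout: int, kernel: int = 3, *, rng: np.random.Generator,
                 dtype=np.float32):
        self.cin, self.cout, self.k = cin, cout, kernel
        self.pad = kernel // 2
        self.weight = Parameter(_he_init(rng, (cout, cin, kernel, kernel), cin * kernel * kernel, dtype))
        self.bias = Parameter(np.zeros(cout, dtype=dtype))
        self._cols = None
        self._xshape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        p, k = self.pad, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (n,c,h,w,k,k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        cols = np.ascontiguousarray(cols)
        wm = self.weight.value.reshape(self.cout, -1)
        out = cols @ wm.T + self.bias.value
        self._cols, self._xshape = cols, x.shape
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        p, k = self.pad, self.k
        g = np.ascontiguousarray(gout.transpose(0, 2, 3, 1)).reshape(n * h * w, self.cout)
        self.weight.grad += (g.T @ self._cols).reshape(self.weight.value.shape)
        self.bias.grad += g.sum(axis=0)
        self._cols = None
        gsp = g.reshape(n, h, w, self.cout)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=gout.dtype)
        for i in range(k):
            for j in range(k):
                # (n,h,w,cout) @ (cout,cin) -> (n,h,w,cin)
                contrib = gsp @ self.weight.value[:, :, i, j]
                dxp[:, :, i:i + h, j:j + w] += contrib.transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w]


class Conv1d(Module):
    """1-D convolution over (C, L), stride 1, dilation-aware 'same' zero padding."""

    def __init__(self, cin: int, cout: int, kernel: int = 3, dilation: int = 1, *,
                 rng: np.random.Generator, dtype=np.float32):
        self.cin, self.cout, self.k, self.dil = cin, cout, kernel, dilation
        self.pad = dilation * (kernel // 2)
        self.weight = Parameter(_he_init(rng, (cout, cin, kernel), cin * kernel, dtype))
        self.bias = Parameter(np.zeros(cout, dtype=dtype))
        self._xp = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        c, L = x.shape
        p, k, d = self.pad, self.k, self.dil
        xp = np.zeros((c, L + 2 * p), dtype=x.dtype)
        xp[:, p:p + L] = x
        self._xp = xp
        self._L = L
        out = np.empty((self.cout, L), dtype=x.dtype)
        out[:] = self.bias.value[:, None]
        for j in range(k):
            seg = xp[:, j * d:j * d + L]               # (cin, L)
            out += self.weight.value[:, :, j] @ seg
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        p, k, d, L = self.pad, self.k, self.dil, self._L
        xp = self._xp
        self._xp = None
        dxp = np.zeros_like(xp)
        for j in range(k):
            seg = xp[:, j * d:j * d + L]
            self.weight.grad[:, :, j] += gout @ seg.T
            dxp[:, j * d:j * d + L] += self.weight.value[:, :, j].T @ gout
        self.bias.grad += gout.sum(axis=1)
        return dxp[:, p:p + L]


# ---------------------------------------------------------------------------
# normalization


class BatchNorm2d(Module):
    def __init__(self, c: int, *, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Parameter(np.ones(c, dtype=dtype))
        self.beta = Parameter(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std) if train else None
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        self._cache = None
        axes = (0, 2, 3)
        self.gamma.grad += (gout * xhat).sum(axis=axes)
        self.beta.grad += gout.sum(axis=axes)
        m = xhat[:, 0].size  # N*H*W per channel
        gh = gout * self.gamma.value[None, :, None, None]
        gh_mean = gh.mean(axis=axes, keepdims=True)
        ghx_mean = (gh * xhat).mean(axis=axes, keepdims=True)
        return (gh - gh_mean - xhat * ghx_mean) / std[None, :, None, None]


class InstanceNorm1d(Module):
    """Per-channel normalization over the sequence axis of a (C, L) array."""

    def __init__(self, c: int, *, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Parameter(np.ones(c, dtype=dtype))
        self.beta = Parameter(np.zeros(c, dtype=dtype))
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mean = x.mean(axis=1, keepdims=True)
        std = np.sqrt(x.var(axis=1, keepdims=True) + self.eps)
        xhat = (x - mean) / std
        self._cache = (xhat, std)
        return self.gamma.value[:, None] * xhat + self.beta.value[:, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        self._cache = None
        self.gamma.grad += (gout * xhat).sum(axis=1)
        self.beta.grad += gout.sum(axis=1)
        gh = gout * self.gamma.value[:, None]
        gh_mean = gh.mean(axis=1, keepdims=True)
        ghx_mean = (gh * xhat).mean(axis=1, keepdims=True)
        return (gh - gh_mean - xhat * ghx_mean) / std


class LayerNorm(Module):
    """Normalization over the last axis (used inside the transformer layer)."""

    def __init__(self, d: int, *, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Parameter(np.ones(d, dtype=dtype))
        self.beta = Parameter(np.zeros(d, dtype=dtype))
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mean = x.mean(axis=-1, keepdims=True)
        std = np.sqrt(x.var(axis=-1, keepdims=True) + self.eps)
        xhat = (x - mean) / std
        self._cache = (xhat, std)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        self._cache = None
        red = tuple(range(gout.ndim - 1))
        self.gamma.grad += (gout * xhat).sum(axis=red)
        self.beta.grad += gout.sum(axis=red)
        gh = gout * self.gamma.value
        gh_mean = gh.mean(axis=-1, keepdims=True)
        ghx_mean = (gh * xhat).mean(axis=-1, keepdims=True)
        return (gh - gh_mean - xhat * ghx_mean) / std


# ---------------------------------------------------------------------------
# activations / dropout


class ReLU(Module):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        m = self._mask
        self._mask = None
        return gout * m


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.1):
        self.slope = slope

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gout):
        m = self._mask
        self._mask = None
        return np.where(m, gout, self.slope * gout)


class Dropout(Module):
    """Inverted dropout; identity in eval mode. RNG is injected for determinism."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p, self.rng = p, rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, gout):
        if self._mask is None:
            return gout
        m = self._mask
        self._mask = None
        return gout * m


# ---------------------------------------------------------------------------
# pooling


class MaxPool2d(Module):
    """2x2 max pooling, stride 2; trailing odd row/column dropped (floor rule)."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xv = x[:, :, :2 * h2, :2 * w2].reshape(n, c, h2, 2, w2, 2)
        flat = xv.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        idx = flat.argmax(axis=-1)
        self._cache = (x.shape, idx)
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, gout):
        (n, c, h, w), idx = self._cache
        self._cache = None
        h2, w2 = h // 2, w // 2
        gflat = np.zeros((n, c, h2, w2, 4), dtype=gout.dtype)
        np.put_along_axis(gflat, idx[..., None], gout[..., None], axis=-1)
        gx = np.zeros((n, c, h, w), dtype=gout.dtype)
        gv = gflat.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        gx[:, :, :2 * h2, :2 * w2] = gv.reshape(n, c, 2 * h2, 2 * w2)
        return gx


class AvgPool1d(Module):
    """Average pooling over (C, L) with kernel = stride; remainder slices dropped."""

    def __init__(self, kernel: int = 4):
        self.k = kernel

    def forward(self, x, train=False):
        c, L = x.shape
        p = L // self.k
        self._cache = (x.shape, p)
        return x[:, :p * self.k].reshape(c, p, self.k).mean(axis=-1)

    def backward(self, gout):
        (c, L), p = self._cache
        self._cache = None
        gx = np.zeros((c, L), dtype=gout.dtype)
        gx[:, :p * self.k] = np.repeat(gout / self.k, self.k, axis=1)
        return gx


def adaptive_bin_edges(length: int, bins: int) -> np.ndarray:
    """Contiguous near-equal bins; the remainder is spread over the proximal
    bins. Sequences shorter than the bin count leave the distal bins empty."""
    base, rem = divmod(length, bins)
    sizes = np.full(bins, base, dtype=int)
    sizes[:rem] += 1
    return np.concatenate([[0], np.cumsum(sizes)])


class AdaptiveSumPool1d(Module):
    """Sum pooling of (C, L) into a fixed number of contiguous bins
    (an empty distal bin sums to 0 when L < bins)."""

    def __init__(self, bins: int = 5):
        if bins < 1:
            raise ValueError("bins must be >= 1")
        self.bins = bins

    def forward(self, x, train=False):
        c, L = x.shape
        edges = adaptive_bin_edges(L, self.bins)
        csum = np.concatenate([np.zeros((c, 1), dtype=x.dtype), np.cumsum(x, axis=1)],
                              axis=1)
        self._cache = (x.shape, edges)
        return csum[:, edges[1:]] - csum[:, edges[:-1]]

    def backward(self, gout):
        (c, L), edges = self._cache
        self._cache = None
        gx = np.zeros((c, L), dtype=gout.dtype)
        for b in range(self.bins):
            gx[:, edges[b]:edges[b + 1]] = gout[:, b:b + 1]
        return gx


class GlobalAvgPool2d(Module):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gout):
        n, c, h, w = self._shape
        return np.broadcast_to(gout[:, :, None, None] / (h * w), (n, c, h, w)).copy()


# ---------------------------------------------------------------------------
# dense / attention


class Linear(Module):
    def __init__(self, din: int, dout: int, *, rng: np.random.Generator, dtype=np.float32):
        bound = np.sqrt(1.0 / din)
        self.weight = Parameter(rng.uniform(-bound, bound, (dout, din)).astype(dtype))
        self.bias = Parameter(np.zeros(dout, dtype=dtype))

    def forward(self, x, train=False):
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, gout):
        x = self._x
        self._x = None
        gflat = gout.reshape(-1, gout.shape[-1])
        xflat = x.reshape(-1, x.shape[-1])
        self.weight.grad += gflat.T @ xflat
        self.bias.grad += gflat.sum(axis=0)
        return gout @ self.weight.value


class MultiheadSelfAttention(Module):
    """Self-attention over (L, d) with h heads; no positional encoding."""

    def __init__(self, d: int, heads: int, *, rng: np.random.Generator, dtype=np.float32):
        if d % heads != 0:
            raise ValueError("model width must be divisible by the head count")
        self.d, self.h, self.dh = d, heads, d // heads
        self.wq = Linear(d, d, rng=rng, dtype=dtype)
        self.wk = Linear(d, d, rng=rng, dtype=dtype)
        self.wv = Linear(d, d, rng=rng, dtype=dtype)
        self.wo = Linear(d, d, rng=rng, dtype=dtype)

    def _split(self, x):  # (L, d) -> (h, L, dh)
        L = x.shape[0]
        return x.reshape(L, self.h, self.dh).transpose(1, 0, 2)

    def forward(self, x, train=False):
        q = self._split(self.wq.forward(x, train))
        k = self._split(self.wk.forward(x, train))
        v = self._split(self.wv.forward(x, train))
        scale = 1.0 / np.sqrt(self.dh)
        scores = (q @ k.transpose(0, 2, 1)) * scale       # (h, L, L)
        scores -= scores.max(axis=-1, keepdims=True)
        attn = np.exp(scores)
        attn /= attn.sum(axis=-1, keepdims=True)
        ctx = attn @ v                                     # (h, L, dh)
        L = x.shape[0]
        self._cache = (q, k, v, attn, scale, L)
        return self.wo.forward(ctx.transpose(1, 0, 2).reshape(L, self.d), train)

    def backward(self, gout):
        q, k, v, attn, scale, L = self._cache
        self._cache = None
        gctx = self.wo.backward(gout).reshape(L, self.h, self.dh).transpose(1, 0, 2)
        gattn = gctx @ v.transpose(0, 2, 1)                # (h, L, L)
        gv = attn.transpose(0, 2, 1) @ gctx
        gscores = attn * (gattn - (gattn * attn).sum(axis=-1, keepdims=True))
        gq = (gscores @ k) * scale
        gk = (gscores.transpose(0, 2, 1) @ q) * scale

        def merge(a):  # (h, L, dh) -> (L, d)
            return a.transpose(1, 0, 2).reshape(L, self.d)

        gx = self.wq.backward(merge(gq))
        gx = gx + self.wk.backward(merge(gk))
        gx = gx + self.wv.backward(merge(gv))
        return gx


class TransformerEncoderLayer(Module):
    """Post-norm transformer encoder block: MHA + residual + LN, FFN + residual + LN.

    Operates on (L, d); no positional encoding (the sum-pooling heads downstream
    are order-aware through their binning, and convolutions upstream already
    encode locality).
    """

    def __init__(self, d: int, heads: int, ff_dim: int | None = None, *,
                 rng: np.random.Generator, dtype=np.float32):
        ff_dim = ff_dim or 2 * d
        self.attn = MultiheadSelfAttention(d, heads, rng=rng, dtype=dtype)
        self.ln1 = LayerNorm(d, dtype=dtype)
        self.ff1 = Linear(d, ff_dim, rng=rng, dtype=dtype)
        self.act = ReLU()
        self.ff2 = Linear(ff_dim, d, rng=rng, dtype=dtype)
        self.ln2 = LayerNorm(d, dtype=dtype)

    def forward(self, x, train=False):
        y = self.ln1.forward(x + self.attn.forward(x, train), train)
        z = self.ff2.forward(self.act.forward(self.ff1.forward(y, train), train), train)
        return self.ln2.forward(y + z, train)

    def backward(self, gout):
        g = self.ln2.backward(gout)
        gz = self.ff1.backward(self.act.backward(self.ff2.backward(g)))
        gy = g + gz
        g1 = self.ln1.backward(gy)
        return g1 + self.attn.backward(g1)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gout):
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout
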