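"""Minimal CPU neural-network engine used by the segmentation model.

Layers are NumPy modules with explicit ``forward``/``backward`` methods;
convolutions are evaluated as one GEMM per kernel tap (``tensordot`` against a
strided view of the padded input), which handles stride and dilation without
materialising an im2col buffer and keeps the heavy lifting inside BLAS.  All
tensors are NCHW ``float32``.

This engine implements exactly what the segmentation architecture needs:
2-D convolution (arbitrary stride/dilation), batch normalisation, ReLU,
3×3/stride-2 max pooling, dropout, global average pooling, and separable
bilinear resizing, each with a hand-derived backward pass.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "Dropout",
    "GlobalAvgPool",
    "BilinearResize",
    "softmax_cross_entropy",
]

_F32 = np.float32


class Parameter:
    """A trainable array with an accumulated gradient.

    ``decay`` marks whether weight decay applies; convolution kernels decay,
    normalisation scales/offsets and biases do not (the usual convention).
    """

    __slots__ = ("data", "grad", "decay")

    def __init__(self, data: np.ndarray, decay: bool = True):
        self.data = np.ascontiguousarray(data, dtype=_F32)
        self.grad = np.zeros_like(self.data)
        self.decay = decay


class Module:
    """Base class: tracks child modules/parameters in construction order."""

    def __init__(self) -> None:
        self._mods: list[Module] = []
        self._params: list[Parameter] = []
        self._buffers: list[np.ndarray] = []

    def add(self, mod: "Module") -> "Module":
        self._mods.append(mod)
        return mod

    def parameters(self) -> list[Parameter]:
        out = list(self._params)
        for m in self._mods:
            out.extend(m.parameters())
        return out

    def buffers(self) -> list[np.ndarray]:
        out = list(self._buffers)
        for m in self._mods:
            out.extend(m.buffers())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for m in mods:
            self.add(m)

    def forward(self, x, train=False):
        for m in self._mods:
            x = m.forward(x, train)
        return x

    def backward(self, grad):
        for m in reversed(self._mods):
            grad = m.backward(grad)
        return grad


def _tap_slices(i: int, j: int, d: int, s: int, ho: int, wo: int):
    return (
        slice(i * d, i * d + s * (ho - 1) + 1, s),
        slice(j * d, j * d + s * (wo - 1) + 1, s),
    )


class Conv2d(Module):
    """2-D convolution with 'same'-style padding for odd kernels.

    Padding defaults to ``dilation * (k - 1) // 2`` so stride-1 convolutions
    preserve the spatial size for any dilation.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int,
        stride: int = 1,
        dilation: int = 1,
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        if k < 1 or stride < 1 or dilation < 1:
            raise InputError("kernel, stride and dilation must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.dilation = stride, dilation
        self.pad = dilation * (k - 1) // 2
        std = np.sqrt(2.0 / (cout * k * k))  # He fan-out
        self.weight = Parameter(rng.normal(0.0, std, size=(cout, cin, k, k)))
        self._params.append(self.weight)
        self.bias = None
        if bias:
            self.bias = Parameter(np.zeros(cout), decay=False)
            self._params.append(self.bias)
        self._xp: np.ndarray | None = None
        self._xshape: tuple | None = None

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        eff = self.dilation * (self.k - 1) + 1
        return (
            (h + 2 * self.pad - eff) // self.stride + 1,
            (w + 2 * self.pad - eff) // self.stride + 1,
        )

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if c != self.cin:
            raise InputError(f"expected {self.cin} input channels, got {c}")
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho, wo = self._out_hw(h, w)
        acc = np.zeros((self.cout, n, ho, wo), dtype=_F32)
        for i in range(self.k):
            for j in range(self.k):
                si, sj = _tap_slices(i, j, self.dilation, self.stride, ho, wo)
                acc += np.tensordot(
                    self.weight.data[:, :, i, j], xp[:, :, si, sj], axes=([1], [1])
                )
        out = np.ascontiguousarray(acc.transpose(1, 0, 2, 3))
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        if train:
            self._xp, self._xshape = xp, x.shape
        else:
            self._xp = self._xshape = None
        return out

    def backward(self, grad):
        if self._xp is None:
            raise RuntimeError("backward called without a cached training forward")
        n, c, h, w = self._xshape
        ho, wo = grad.shape[2], grad.shape[3]
        g = np.ascontiguousarray(grad.transpose(1, 0, 2, 3))  # (cout,N,Ho,Wo)
        gxp = np.zeros((c, n, self._xp.shape[2], self._xp.shape[3]), dtype=_F32)
        for i in range(self.k):
            for j in range(self.k):
                si, sj = _tap_slices(i, j, self.dilation, self.stride, ho, wo)
                v = self._xp[:, :, si, sj]  # (N,cin,Ho,Wo)
                self.weight.grad[:, :, i, j] += np.tensordot(
                    g, v, axes=([1, 2, 3], [0, 2, 3])
                )
                gxp[:, :, si, sj] += np.tensordot(
                    self.weight.data[:, :, i, j], g, axes=([0], [0])
                )
        if self.bias is not None:
            self.bias.grad += g.sum(axis=(1, 2, 3))
        p = self.pad
        gx = gxp[:, :, p : p + h, p : p + w] if p else gxp
        return np.ascontiguousarray(gx.transpose(1, 0, 2, 3))


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(c), decay=False)
        self.beta = Parameter(np.zeros(c), decay=False)
        self._params += [self.gamma, self.beta]
        self.running_mean = np.zeros(c, dtype=_F32)
        self.running_var = np.ones(c, dtype=_F32)
        self._buffers += [self.running_mean, self.running_var]
        self._xhat = self._inv = None

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = x.shape[0] * x.shape[2] * x.shape[3]
            self.running_mean += self.momentum * (mean - self.running_mean)
            unbiased = var * m / max(m - 1, 1)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        xhat = xhat.astype(_F32, copy=False)
        if train:
            self._xhat, self._inv = xhat, inv.astype(_F32)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[
            None, :, None, None
        ]

    def backward(self, grad):
        xhat, inv = self._xhat, self._inv
        axes = (0, 2, 3)
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        dxhat = grad * self.gamma.data[None, :, None, None]
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        mean_d = dxhat.mean(axis=axes)
        mean_dx = (dxhat * xhat).mean(axis=axes)
        dx = inv[None, :, None, None] * (
            dxhat
            - mean_d[None, :, None, None]
            - xhat * mean_dx[None, :, None, None]
        )
        return dx.astype(_F32, copy=False)


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x, train=False):
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, _F32(0.0))

    def backward(self, grad):
        return np.where(self._mask, grad, _F32(0.0))


class MaxPool2d(Module):
    """k×k max pooling (default 3×3, stride 2, pad 1, as in a ResNet stem)."""

    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad
        self._idx = None
        self._shape = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        ho = (h + 2 * p - self.k) // self.stride + 1
        wo = (w + 2 * p - self.k) // self.stride + 1
        taps = np.stack(
            [
                xp[(slice(None), slice(None)) + _tap_slices(i, j, 1, self.stride, ho, wo)]
                for i in range(self.k)
                for j in range(self.k)
            ]
        )
        idx = taps.argmax(axis=0)
        if train:
            self._idx, self._shape = idx, (n, c, h, w)
        return taps.max(axis=0)

    def backward(self, grad):
        n, c, h, w = self._shape
        p = self.pad
        gxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=_F32)
        ho, wo = grad.shape[2], grad.shape[3]
        for t in range(self.k * self.k):
            i, j = divmod(t, self.k)
            si, sj = _tap_slices(i, j, 1, self.stride, ho, wo)
            gxp[:, :, si, sj] += np.where(self._idx == t, grad, _F32(0.0))
        return gxp[:, :, p : p + h, p : p + w]


class Dropout(Module):
    def __init__(self, p: float = 0.1):
        super().__init__()
        self.p = p
        self.rng = np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(_F32) / _F32(keep)
        self._mask = mask
        return x * mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class GlobalAvgPool(Module):
    def __init__(self):
        super().__init__()
        self._hw = None

    def forward(self, x, train=False):
        if train:
            self._hw = x.shape[2:]
        return x.mean(axis=(2, 3), keepdims=True).astype(_F32, copy=False)

    def backward(self, grad):
        h, w = self._hw
        scale = _F32(1.0 / (h * w))
        return np.broadcast_to(grad * scale, grad.shape[:2] + (h, w)).astype(_F32)


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-interpolation matrix for half-pixel-centre bilinear resampling."""
    if n_in == 1:
        return np.ones((n_out, 1), dtype=_F32)
    src = (np.arange(n_out, dtype=np.float64) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = src - i0
    a = np.zeros((n_out, n_in), dtype=np.float64)
    rows = np.arange(n_out)
    np.add.at(a, (rows, i0), 1.0 - w1)
    np.add.at(a, (rows, i1), w1)
    return a.astype(_F32)


class BilinearResize(Module):
    """Separable bilinear resize to a target size given at call time."""

    def __init__(self):
        super().__init__()
        self._cache: dict[tuple[int, int], np.ndarray] = {}
        self._last: tuple | None = None

    def _matrix(self, n_in: int, n_out: int) -> np.ndarray:
        key = (n_in, n_out)
        if key not in self._cache:
            self._cache[key] = _interp_matrix(n_in, n_out)
        return self._cache[key]

    def forward(self, x, out_hw: tuple[int, int] = None, train: bool = False):
        if out_hw is None:
            raise InputError("BilinearResize.forward requires out_hw")
        ah = self._matrix(x.shape[2], out_hw[0])
        aw = self._matrix(x.shape[3], out_hw[1])
        if train:
            self._last = (ah, aw)
        y = np.einsum("ah,nchw->ncaw", ah, x, optimize=True)
        return np.einsum("bw,ncaw->ncab", aw, y, optimize=True).astype(_F32, copy=False)

    def backward(self, grad):
        ah, aw = self._last
        g = np.einsum("bw,ncab->ncaw", aw, grad, optimize=True)
        return np.einsum("ah,ncaw->nchw", ah, g, optimize=True).astype(_F32, copy=False)


def softmax_cross_entropy(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean per-pixel cross-entropy and its gradient w.r.t. the scores.

    ``scores`` is (N, K, H, W); ``labels`` is (N, H, W) with integer classes.
    """
    n, k, h, w = scores.shape
    if labels.shape != (n, h, w):
        raise InputError(f"labels shape {labels.shape} does not match scores")
    if labels.min() < 0 or labels.max() >= k:
        raise InputError(f"labels must lie in [0, {k - 1}]")
    z = scores - scores.max(axis=1, keepdims=True)
    ez = np.exp(z)
    sez = ez.sum(axis=1, keepdims=True)
    logp = z - np.log(sez)
    picked = np.take_along_axis(logp, labels[:, None], axis=1)[:, 0]
    loss = float(-picked.mean())
    m = n * h * w
    grad = ez / sez
    nidx = np.arange(n)[:, None, None]
    hidx = np.arange(h)[None, :, None]
    widx = np.arange(w)[None, None, :]
    grad[nidx, labels, hidx, widx] -= 1.0
    grad /= _F32(m)
    return loss, grad.astype(_F32, copy=False)
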