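"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based autodiff core: each op returns a new
:class:`Tensor` holding the result and a closure that propagates gradients to
its inputs. Real tensors are float64; a restricted set of spectral ops
(:func:`fft2`, :func:`ifft2`, :func:`cmul`, :func:`cabs`) produce complex128
tensors whose "gradient" follows the convention ``g = dL/dRe + 1j * dL/dIm``
for a real-valued loss L.
"""

from __future__ import annotations

import contextlib

import numpy as np

DEFAULT_DTYPE = np.float64

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # Sum over leading dims that were added by broadcasting.
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # Sum over axes that were 1 in the original shape.
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if np.issubdtype(arr.dtype, np.complexfloating):
            arr = arr.astype(np.complex128, copy=False)
        else:
            arr = arr.astype(DEFAULT_DTYPE, copy=False)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = ()
        self.name = None

    # ---- bookkeeping -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data.reshape(-1)[0].real) if self.data.size == 1 else float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if np.issubdtype(self.data.dtype, np.floating) and np.iscomplexobj(g):
            g = g.real
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or g.flags.writeable is False else g
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in seen:
                    stack.append((child, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        return self

    # ---- graph construction ---------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: tuple, backward) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out.name = None
        track = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out.requires_grad = track
        if track:
            out._prev = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        else:
            out._prev = ()
            out._backward = None
        return out

    # ---- elementwise arithmetic ------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            a._accumulate(-g)

        return Tensor._make(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * np.conj(b.data), a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * np.conj(a.data), b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        a = self

        def bw(g):
            a._accumulate(g * p * a.data ** (p - 1))

        return Tensor._make(a.data**p, (a,), bw)

    # ---- unary -----------------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._accumulate(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bw)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bw(g):
            a._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), bw)

    def abs(self):
        """Absolute value of a real tensor (see :func:`cabs` for complex)."""
        a = self

        def bw(g):
            a._accumulate(g * np.sign(a.data))

        return Tensor._make(np.abs(a.data), (a,), bw)

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))

        def bw(g):
            a._accumulate(g * s * (1.0 - s))

        return Tensor._make(s, (a,), bw)

    def tanh(self):
        a = self
        t = np.tanh(a.data)

        def bw(g):
            a._accumulate(g * (1.0 - t * t))

        return Tensor._make(t, (a,), bw)

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            a._accumulate(g * mask)

        return Tensor._make(a.data * mask, (a,), bw)

    def silu(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))
        out_data = a.data * s

        def bw(g):
            a._accumulate(g * (s + out_data * (1.0 - s)))

        return Tensor._make(out_data, (a,), bw)

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        from scipy.special import erf

        a = self
        cdf = 0.5 * (1.0 + erf(a.data / np.sqrt(2.0)))

        def bw(g):
            pdf = np.exp(-0.5 * a.data * a.data) / np.sqrt(2.0 * np.pi)
            a._accumulate(g * (cdf + a.data * pdf))

        return Tensor._make(a.data * cdf, (a,), bw)

    # ---- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                gg = np.broadcast_to(g, a.data.shape)
            else:
                gshaped = g if keepdims else np.expand_dims(g, axis)
                gg = np.broadcast_to(gshaped, a.data.shape)
            a._accumulate(gg)

        return Tensor._make(out_data, (a,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims=False):
        a = self
        out_data = a.data.max(axis=axis, keepdims=keepdims)

        def bw(g):
            gshaped = g if (keepdims or axis is None) else np.expand_dims(g, axis)
            oshaped = out_data if (keepdims or axis is None) else np.expand_dims(out_data, axis)
            mask = a.data == oshaped
            # split gradient among ties
            counts = mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
            a._accumulate(gshaped * mask / counts)

        return Tensor._make(out_data, (a,), bw)

    # ---- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def bw(g):
            a._accumulate(g.reshape(old))

        return Tensor._make(a.data.reshape(shape), (a,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def bw(g):
            a._accumulate(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bw)

    def __getitem__(self, idx):
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accumulate(full)

        return Tensor._make(a.data[idx], (a,), bw)

    # ---- linear algebra ----------------------------------------------------
    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), bw)

    def softmax(self, axis=-1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            a._accumulate(s * (g - dot))

        return Tensor._make(s, (a,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(data, tuple(tensors), bw)


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return Tensor._make(data, tuple(tensors), bw)


def pad2d(x: Tensor, pad_h: int, pad_w: int) -> Tensor:
    """Zero-pad the last two axes symmetrically."""
    if pad_h == 0 and pad_w == 0:
        return x
    a = x
    widths = [(0, 0)] * (a.ndim - 2) + [(pad_h, pad_h), (pad_w, pad_w)]
    data = np.pad(a.data, widths)
    H, W = a.data.shape[-2:]

    def bw(g):
        sl = (Ellipsis, slice(pad_h, pad_h + H), slice(pad_w, pad_w + W))
        a._accumulate(g[sl])

    return Tensor._make(data, (a,), bw)


# ---- spectral ops -----------------------------------------------------------
# Convention: unnormalized forward FFT, 1/(H*W)-normalized inverse (numpy
# default). Gradients use g = dL/dRe + 1j*dL/dIm; for the linear map y = F x
# the pullback is F^H g, i.e. N*ifft2 for fft2 and fft2/N for ifft2.


def fft2(x: Tensor) -> Tensor:
    a = x
    data = np.fft.fft2(a.data, axes=(-2, -1))

    def bw(g):
        n = a.data.shape[-2] * a.data.shape[-1]
        ga = np.fft.ifft2(g, axes=(-2, -1)) * n
        a._accumulate(ga)

    return Tensor._make(data, (a,), bw)


def ifft2(x: Tensor) -> Tensor:
    a = x
    data = np.fft.ifft2(a.data, axes=(-2, -1))

    def bw(g):
        n = a.data.shape[-2] * a.data.shape[-1]
        ga = np.fft.fft2(g, axes=(-2, -1)) / n
        a._accumulate(ga)

    return Tensor._make(data, (a,), bw)


def cmul(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise (possibly complex) product with broadcasting.

    Same pullback rule as ``__mul__`` (which already conjugates); provided as
    a named op for readability in spectral code paths.
    """
    return as_tensor(a) * as_tensor(b)


def cabs(x: Tensor, eps: float = 1e-12) -> Tensor:
    """Magnitude of a complex tensor, differentiable away from zero."""
    a = x
    mag = np.abs(a.data)

    def bw(g):
        a._accumulate(g.real * a.data / np.maximum(mag, eps))

    return Tensor._make(mag, (a,), bw)
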