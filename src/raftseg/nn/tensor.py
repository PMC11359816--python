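"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: every operation returns a new
:class:`Tensor` holding the result plus a closure that propagates the
upstream gradient to its inputs.  ``Tensor.backward()`` runs the tape in
reverse topological order.  Only the primitives required by the
segmentation network are provided (element-wise arithmetic, matmul,
shape surgery, 2-D convolution with groups and stride, max pooling,
bilinear upsampling and the usual activations).

All computation is plain numpy, so results are bit-reproducible for a
fixed seed regardless of the host.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf, expit

__all__ = ["Tensor", "concatenate", "conv2d", "max_pool2d", "upsample_bilinear2x"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an attached gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debug aid
        return f"Tensor(shape={self.shape}, grad={'set' if self.grad is not None else 'none'})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.result_type(self.data.dtype, np.float32))
        self.grad += g

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- construction helpers ------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req, _prev=tuple(p for p in parents if p.requires_grad))
        if req:
            out._backward = backward
        return out

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / (other.data ** 2), other.shape))

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        return self._make(out_data, (self, other), backward)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape surgery -------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accumulate(g.reshape(old))

        return self._make(out_data, (self,), backward)

    def transpose(self, axes):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out_data = self.data.transpose(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accumulate(full)

        return self._make(out_data, (self,), backward)

    def pad_axis(self, axis: int, before: int, after: int):
        """Zero-pad one axis."""
        widths = [(0, 0)] * self.ndim
        widths[axis] = (before, after)
        out_data = np.pad(self.data, widths)
        sl = [slice(None)] * self.ndim
        sl[axis] = slice(before, before + self.shape[axis])
        sl = tuple(sl)

        def backward(g):
            self._accumulate(g[sl])

        return self._make(out_data, (self,), backward)

    # -- activations and point-wise functions --------------------------
    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def backward(g):
            self._accumulate(g * mask)

        return self._make(out_data, (self,), backward)

    def gelu(self):
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out_data = x * cdf

        def backward(g):
            pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
            self._accumulate(g * (cdf + x * pdf))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = expit(self.data)

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            self._accumulate(g / self.data)

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accumulate(g * 0.5 / out_data)

        return self._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through unclamped entries."""
        mask = (self.data > lo) & (self.data < hi)
        out_data = np.clip(self.data, lo, hi)

        def backward(g):
            self._accumulate(g * mask)

        return self._make(out_data, (self,), backward)

    def detach(self):
        return Tensor(self.data.copy())


# ----------------------------------------------------------------------
def concatenate(tensors: list, axis: int) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    req = any(t.requires_grad for t in tensors)
    out = Tensor(out_data, requires_grad=req, _prev=tuple(t for t in tensors if t.requires_grad))
    if req:
        out._backward = backward
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation with square stride/padding and channel groups.

    ``x``: (B, Cin, H, W); ``weight``: (Cout, Cin // groups, kh, kw);
    ``bias``: (Cout,) or None.  Depthwise convolution is ``groups == Cin``
    with ``Cout == Cin``.
    """
    x = Tensor._lift(x)
    B, Cin, H, W = x.shape
    Cout, Cin_g, kh, kw = weight.shape
    if Cin % groups or Cout % groups or Cin // groups != Cin_g:
        raise ValueError(
            f"conv2d group mismatch: Cin={Cin}, Cout={Cout}, groups={groups}, weight Cin/g={Cin_g}"
        )
    if isinstance(padding, int):
        ph = pw = padding
    else:
        ph, pw = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    Hp, Wp = xp.shape[2:]
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    # windows: (B, Cin, Ho, Wo, kh, kw)
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    wing = win.reshape(B, groups, Cin_g, Ho, Wo, kh, kw)
    wg = weight.data.reshape(groups, Cout // groups, Cin_g, kh, kw)
    out_data = np.einsum("bgihwkl,goikl->bgohw", wing, wg, optimize=True)
    out_data = out_data.reshape(B, Cout, Ho, Wo)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]

    parents = [p for p in (x, weight, bias) if p is not None]

    def backward(g):
        gg = g.reshape(B, groups, Cout // groups, Ho, Wo)
        if weight.requires_grad:
            dw = np.einsum("bgihwkl,bgohw->goikl", wing, gg, optimize=True)
            weight._accumulate(dw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # d(cols) then scatter back into the padded input
            dcols = np.einsum("bgohw,goikl->bgihwkl", gg, wg, optimize=True)
            dcols = dcols.reshape(B, Cin, Ho, Wo, kh, kw)
            dxp = np.zeros_like(xp)
            for ki in range(kh):
                for kj in range(kw):
                    dxp[:, :, ki:ki + stride * Ho:stride, kj:kj + stride * Wo:stride] += dcols[:, :, :, :, ki, kj]
            dx = dxp[:, :, ph:ph + H, pw:pw + W]
            x._accumulate(dx)

    req = any(p.requires_grad for p in parents)
    out = Tensor(out_data, requires_grad=req, _prev=tuple(p for p in parents if p.requires_grad))
    if req:
        out._backward = backward
    return out


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    """Max pooling; padding uses -inf so padded cells never win."""
    x = Tensor._lift(x)
    B, C, H, W = x.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf)
    Ho = (xp.shape[2] - kernel) // stride + 1
    Wo = (xp.shape[3] - kernel) // stride + 1
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    flat = win.reshape(B, C, Ho, Wo, kernel * kernel)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        bi, ci, oi, oj = np.indices((B, C, Ho, Wo))
        ri = oi * stride - padding + idx // kernel
        cj = oj * stride - padding + idx % kernel
        dx = np.zeros_like(x.data)
        np.add.at(dx, (bi, ci, ri, cj), g)
        x._accumulate(dx)

    out = Tensor(out_data, requires_grad=x.requires_grad,
                 _prev=(x,) if x.requires_grad else ())
    if x.requires_grad:
        out._backward = backward
    return out


def _bilinear_weights(n_out: int, n_in: int):
    """Half-pixel-centre bilinear gather indices/weights (align_corners=False)."""
    coords = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    coords = np.clip(coords, 0, n_in - 1)
    i0 = np.floor(coords).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = coords - i0
    w0 = 1.0 - w1
    return i0, i1, w0, w1


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Bilinear 2x spatial upsampling of a (B, C, H, W) map."""
    x = Tensor._lift(x)
    B, C, H, W = x.shape
    ri0, ri1, rw0, rw1 = _bilinear_weights(2 * H, H)
    ci0, ci1, cw0, cw1 = _bilinear_weights(2 * W, W)
    d = x.data
    rows = d[:, :, ri0, :] * rw0[None, None, :, None] + d[:, :, ri1, :] * rw1[None, None, :, None]
    out_data = rows[:, :, :, ci0] * cw0[None, None, None, :] + rows[:, :, :, ci1] * cw1[None, None, None, :]

    def backward(g):
        drows = np.zeros((B, C, 2 * H, W), dtype=g.dtype)
        np.add.at(drows, (slice(None), slice(None), slice(None), ci0), g * cw0[None, None, None, :])
        np.add.at(drows, (slice(None), slice(None), slice(None), ci1), g * cw1[None, None, None, :])
        dx = np.zeros_like(x.data)
        np.add.at(dx, (slice(None), slice(None), ri0, slice(None)), drows * rw0[None, None, :, None])
        np.add.at(dx, (slice(None), slice(None), ri1, slice(None)), drows * rw1[None, None, :, None])
        x._accumulate(dx)

    out = Tensor(out_data, requires_grad=x.requires_grad,
                 _prev=(x,) if x.requires_grad else ())
    if x.requires_grad:
        out._backward = backward
    return out
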