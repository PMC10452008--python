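"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains convolutional networks on the CPU, so the engine is a
deliberately small tensor/graph core: a :class:`Tensor` wraps a float64
numpy array, records its parents and a backward closure when gradients are
enabled, and :meth:`Tensor.backward` runs the reverse topological sweep.
Convolutions are im2col + batched matmul; pooling shares the same window
extraction. Only the operations the segmentation network needs exist here.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "SGD",
    "no_grad",
    "concatenate",
    "conv2d",
    "conv_transpose2d",
    "maxpool2d",
    "avgpool2d",
    "softmax",
    "relu",
]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverses numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing ------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray):
        grad = np.asarray(grad, dtype=np.float64)
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad = self.grad + grad

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
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
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- basics --------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: a._accumulate(-g))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._coerce(other) ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, p: float):
        a = self
        out_data = a.data ** p

        def backward(g):
            a._accumulate(g * p * a.data ** (p - 1.0))

        return Tensor._make(out_data, (a,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return Tensor._make(a.data @ b.data, (a, b), backward)

    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(out_data, (a,), lambda g: a._accumulate(g * out_data))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: a._accumulate(g / a.data))

    def sqrt(self):
        return self ** 0.5

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape))

        return Tensor._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[i] for i in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape
        return Tensor._make(
            a.data.reshape(shape), (a,), lambda g: a._accumulate(g.reshape(old))
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)
        return Tensor._make(
            a.data.transpose(axes), (a,), lambda g: a._accumulate(g.transpose(inv))
        )

    def __getitem__(self, idx):
        a = self

        def backward(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accumulate(full)

        return Tensor._make(a.data[idx], (a,), backward)


class Parameter(Tensor):
    """A trainable tensor (always requires grad)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor._make(x.data * mask, (x,), lambda g: x._accumulate(g * mask))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accumulate(y * (g - dot))

    return Tensor._make(y, (x,), backward)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(data, tuple(tensors), backward)


# -- window extraction ------------------------------------------------


def _out_hw(H, W, kh, kw, stride, pad):
    return (H + 2 * pad - kh) // stride + 1, (W + 2 * pad - kw) // stride + 1


def _im2col(x: np.ndarray, kh, kw, stride, pad, pad_value=0.0) -> np.ndarray:
    """(B,C,H,W) -> (B, C*kh*kw, Ho*Wo) patch matrix."""
    B, C, H, W = x.shape
    Ho, Wo = _out_hw(H, W, kh, kw, stride, pad)
    if pad:
        x = np.pad(
            x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=pad_value
        )
    sB, sC, sH, sW = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(B, C, kh, kw, Ho, Wo),
        strides=(sB, sC, sH, sW, sH * stride, sW * stride),
        writeable=False,
    )
    return np.ascontiguousarray(windows).reshape(B, C * kh * kw, Ho * Wo)


def _col2im(cols: np.ndarray, x_shape, kh, kw, stride, pad) -> np.ndarray:
    """Scatter-add inverse of :func:`_im2col`."""
    B, C, H, W = x_shape
    Ho, Wo = _out_hw(H, W, kh, kw, stride, pad)
    cols = cols.reshape(B, C, kh, kw, Ho, Wo)
    out = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += (
                cols[:, :, i, j]
            )
    return out[:, :, pad : pad + H, pad : pad + W]


# -- structured ops ----------------------------------------------------


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
) -> Tensor:
    """2-D cross-correlation; weight is (Cout, Cin/groups, kh, kw)."""
    B, Cin, H, W = x.data.shape
    Cout, Cin_g, kh, kw = weight.data.shape
    if Cin_g * groups != Cin:
        raise ValueError(
            f"conv2d channel mismatch: input has {Cin} channels, "
            f"weight expects {Cin_g * groups} (groups={groups})"
        )
    Ho, Wo = _out_hw(H, W, kh, kw, stride, padding)
    L = Ho * Wo
    cols = _im2col(x.data, kh, kw, stride, padding)
    cols_g = cols.reshape(B, groups, Cin_g * kh * kw, L)
    w_g = weight.data.reshape(groups, Cout // groups, Cin_g * kh * kw)
    out = np.matmul(w_g, cols_g)  # (B, groups, Cout/groups, L)
    out = out.reshape(B, Cout, Ho, Wo)
    if bias is not None:
        out = out + bias.data.reshape(1, Cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        go = g.reshape(B, groups, Cout // groups, L)
        if weight.requires_grad:
            gw = np.matmul(go, np.swapaxes(cols_g, -1, -2)).sum(axis=0)
            weight._accumulate(gw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.matmul(np.swapaxes(w_g, -1, -2), go)
            gcols = gcols.reshape(B, Cin * kh * kw, L)
            x._accumulate(_col2im(gcols, x.data.shape, kh, kw, stride, padding))

    return Tensor._make(out, parents, backward)


def conv_transpose2d(
    x: Tensor, weight: Tensor, bias: Tensor | None = None, stride: int = 2
) -> Tensor:
    """Transposed convolution; weight is (Cin, Cout, kh, kw), no padding."""
    B, Cin, H, W = x.data.shape
    Cin_w, Cout, kh, kw = weight.data.shape
    if Cin_w != Cin:
        raise ValueError(
            f"conv_transpose2d channel mismatch: input {Cin} vs weight {Cin_w}"
        )
    Ho = (H - 1) * stride + kh
    Wo = (W - 1) * stride + kw
    w_flat = weight.data.reshape(Cin, Cout * kh * kw)
    x_flat = x.data.reshape(B, Cin, H * W)
    cols = np.matmul(w_flat.T, x_flat)
    out = _col2im(cols, (B, Cout, Ho, Wo), kh, kw, stride, 0)
    if bias is not None:
        out = out + bias.data.reshape(1, Cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gcols = _im2col(g, kh, kw, stride, 0)  # (B, Cout*kh*kw, H*W)
        if x.requires_grad:
            gx = np.matmul(w_flat, gcols)
            x._accumulate(gx.reshape(x.data.shape))
        if weight.requires_grad:
            gw = np.matmul(x_flat, np.swapaxes(gcols, -1, -2)).sum(axis=0)
            weight._accumulate(gw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor._make(out, parents, backward)


def maxpool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    B, C, H, W = x.data.shape
    Ho, Wo = _out_hw(H, W, kernel, kernel, stride, padding)
    cols = _im2col(x.data, kernel, kernel, stride, padding, pad_value=-np.inf)
    cols = cols.reshape(B, C, kernel * kernel, Ho * Wo)
    idx = cols.argmax(axis=2)
    out = np.take_along_axis(cols, idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(g):
        gcols = np.zeros_like(cols)
        np.put_along_axis(
            gcols, idx[:, :, None, :], g.reshape(B, C, 1, Ho * Wo), axis=2
        )
        gcols = gcols.reshape(B, C * kernel * kernel, Ho * Wo)
        x._accumulate(_col2im(gcols, x.data.shape, kernel, kernel, stride, padding))

    return Tensor._make(out.reshape(B, C, Ho, Wo), (x,), backward)


def avgpool2d(x: Tensor, kernel: int, stride: int) -> Tensor:
    B, C, H, W = x.data.shape
    Ho, Wo = _out_hw(H, W, kernel, kernel, stride, 0)
    cols = _im2col(x.data, kernel, kernel, stride, 0)
    cols = cols.reshape(B, C, kernel * kernel, Ho * Wo)
    out = cols.mean(axis=2).reshape(B, C, Ho, Wo)

    def backward(g):
        gcols = np.broadcast_to(
            g.reshape(B, C, 1, Ho * Wo) / (kernel * kernel),
            (B, C, kernel * kernel, Ho * Wo),
        ).reshape(B, C * kernel * kernel, Ho * Wo)
        x._accumulate(_col2im(gcols, x.data.shape, kernel, kernel, stride, 0))

    return Tensor._make(out, (x,), backward)


# -- modules and optimizer ---------------------------------------------


class Module:
    """Base class: parameter discovery and train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params, seen = [], set()
        for obj in self.__dict__.values():
            for p in _collect_params(obj):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for obj in self.__dict__.values():
            mods.extend(_collect_modules(obj))
        return mods

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- flat state dict (ordered by discovery) --

    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            arrays.extend(m._buffers())
        return arrays

    def load_state_arrays(self, arrays):
        targets = self.parameters()
        buffers = []
        for m in self.modules():
            buffers.extend(m._buffers())
        slots = targets + buffers
        if len(arrays) != len(slots):
            raise ValueError(
                f"state mismatch: checkpoint has {len(arrays)} arrays, "
                f"model expects {len(slots)}"
            )
        for slot, arr in zip(targets, arrays[: len(targets)]):
            if slot.data.shape != arr.shape:
                raise ValueError("parameter shape mismatch in checkpoint")
            slot.data = np.asarray(arr, dtype=np.float64)
        for buf, arr in zip(buffers, arrays[len(targets) :]):
            buf[...] = arr

    def _buffers(self) -> list[np.ndarray]:
        """Non-trainable persistent arrays (e.g. running statistics)."""
        return []


def _collect_params(obj):
    if isinstance(obj, Parameter):
        yield obj
    elif isinstance(obj, Module):
        yield from obj.parameters()
    elif isinstance(obj, (list, tuple)):
        for item in obj:
            yield from _collect_params(item)


def _collect_modules(obj):
    if isinstance(obj, Module):
        yield from obj.modules()
    elif isinstance(obj, (list, tuple)):
        for item in obj:
            yield from _collect_modules(item)


class SGD:
    """Stochastic gradient descent with classical momentum and L2 weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.0, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None
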