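"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations that
produced it; :meth:`Tensor.backward` walks the tape in reverse topological
order and accumulates gradients into every tensor created with
``requires_grad=True``.  The op set is deliberately small — exactly what the
transformer encoder/decoder, the convolutional dense head and the training
losses need — and every op with a non-trivial adjoint is covered by numerical
gradient checks in the test suite.

All arithmetic is float64.  Broadcasting follows numpy semantics; gradients
of broadcast operands are reduced back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "no_grad", "is_grad_enabled",
           "default_dtype", "get_default_dtype"]

_GRAD_ENABLED = True
_DEFAULT_DTYPE = np.float64


class default_dtype:
    """Context manager selecting the element type for new tensors.

    float64 is the default; float32 roughly doubles GEMM throughput and is
    used by the packaged desk-scale studies.
    """

    def __init__(self, dtype):
        self.dtype = np.dtype(dtype).type

    def __enter__(self):
        global _DEFAULT_DTYPE
        self._prev = _DEFAULT_DTYPE
        _DEFAULT_DTYPE = self.dtype
        return self

    def __exit__(self, *exc):
        global _DEFAULT_DTYPE
        _DEFAULT_DTYPE = self._prev
        return False


def get_default_dtype():
    return _DEFAULT_DTYPE


class no_grad:
    """Context manager disabling tape recording (inference / evaluation)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(_DEFAULT_DTYPE, copy=False)
    return np.asarray(x, dtype=_DEFAULT_DTYPE)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # so ndarray + Tensor defers to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction of result nodes ------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray, own: bool = False):
        # `own=True` promises `grad` is a freshly allocated array the caller
        # will not reuse, so the first accumulation can take it directly.
        if self.grad is None:
            self.grad = grad if own and isinstance(grad, np.ndarray) \
                else np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- basic properties -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                ga = _unbroadcast(g, self.data.shape)
                self._accumulate(ga, own=ga is not g)
            if other.requires_grad:
                gb = _unbroadcast(g, other.data.shape)
                other._accumulate(gb, own=gb is not g)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g, own=True)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape),
                                 own=True)
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape),
                                  own=True)

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1.0), own=True)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape), own=True)
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape), own=True)

        return Tensor._make(out_data, (self, other), backward)

    def linear(self, weight: "Tensor", bias: "Tensor") -> "Tensor":
        """Fused affine map on the last axis: `self @ weight + bias`.

        Equivalent to the composed ops but runs the forward and both weight
        gradients as single 2-D GEMMs regardless of leading batch axes.
        """
        lead = self.data.shape[:-1]
        fan_in = self.data.shape[-1]
        x2 = self.data.reshape(-1, fan_in)
        out2 = x2 @ weight.data
        out2 += bias.data
        out_data = out2.reshape(*lead, weight.data.shape[1])

        def backward(g):
            g2 = g.reshape(-1, weight.data.shape[1])
            if self.requires_grad:
                self._accumulate((g2 @ weight.data.T).reshape(self.data.shape),
                                 own=True)
            if weight.requires_grad:
                weight._accumulate(x2.T @ g2, own=True)
            if bias.requires_grad:
                bias._accumulate(g2.sum(axis=0), own=True)

        return Tensor._make(out_data, (self, weight, bias), backward)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data, own=True)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data, own=True)

        return Tensor._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data ** 2), own=True)

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data), own=True)

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask, own=True)

        return Tensor._make(self.data * mask, (self,), backward)

    def gelu(self):
        # tanh approximation of GELU; adjoint derived analytically.
        # Written with explicit out= buffers: this runs on every MLP
        # activation and the temporaries dominate otherwise.
        c = np.sqrt(2.0 / np.pi)
        x = self.data
        x2 = x * x
        inner = np.multiply(x2, 0.044715 * c)
        inner += c
        inner *= x
        t = np.tanh(inner, out=inner)
        out_data = t + 1.0
        out_data *= 0.5 * x

        def backward(g):
            if self.requires_grad:
                dinner = np.multiply(x2, 3 * 0.044715 * c, out=x2)
                dinner += c
                sech2 = np.multiply(t, t)
                np.subtract(1.0, sech2, out=sech2)
                dgelu = np.multiply(sech2, dinner, out=sech2)
                dgelu *= 0.5 * x
                dgelu += 0.5 * (1.0 + t)
                self._accumulate(g * dgelu, own=True)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy(),
                                 own=True)
            else:
                gg = g
                if not keepdims:
                    gg = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy(),
                                 own=True)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape manipulation -----------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                gr = g.reshape(orig)
                self._accumulate(np.ascontiguousarray(gr), own=True)

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.ascontiguousarray(g.transpose(inv)),
                                 own=True)

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full, own=True)

        return Tensor._make(out_data, (self,), backward)

    def take_rows(self, indices: np.ndarray):
        """Gather rows (first axis) — embedding-table lookup.

        `indices` may have any shape; the result has shape
        indices.shape + self.shape[1:].
        """
        idx = np.asarray(indices)
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx.reshape(-1), g.reshape(-1, *self.data.shape[1:]))
                self._accumulate(full, own=True)

        return Tensor._make(out_data, (self,), backward)

    def unfold_last(self, size: int, stride: int):
        """Sliding windows over the last axis (im2col for 1-D convolution).

        Returns shape (..., n_windows, size) with
        n_windows = (L - size) // stride + 1.
        """
        L = self.data.shape[-1]
        n_win = (L - size) // stride + 1
        starts = np.arange(n_win) * stride
        gather = starts[:, None] + np.arange(size)[None, :]  # (n_win, size)
        out_data = self.data[..., gather]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                flat = full.reshape(-1, L)
                gflat = g.reshape(-1, n_win, size)
                for w in range(n_win):
                    flat[:, starts[w]:starts[w] + size] += gflat[:, w, :]
                self._accumulate(full, own=True)

        return Tensor._make(out_data, (self,), backward)

    def repeat_last(self, times: int):
        """Repeat each element of the last axis `times` times (nearest upsample)."""
        out_data = np.repeat(self.data, times, axis=-1)

        def backward(g):
            if self.requires_grad:
                gg = g.reshape(*self.data.shape, times).sum(axis=-1)
                self._accumulate(gg, own=True)

        return Tensor._make(out_data, (self,), backward)

    def pad_last(self, before: int, after: int):
        """Zero-pad the last axis."""
        widths = [(0, 0)] * (self.data.ndim - 1) + [(before, after)]
        out_data = np.pad(self.data, widths)
        L = self.data.shape[-1]

        def backward(g):
            if self.requires_grad:
                self._accumulate(g[..., before:before + L])  # view: copy

        return Tensor._make(out_data, (self,), backward)

    # -- softmax / normalization (fused for speed & stability) ------------
    def softmax(self, axis=-1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accumulate(out_data * (g - dot), own=True)

        return Tensor._make(out_data, (self,), backward)

    def log_softmax(self, axis=-1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        sm = np.exp(out_data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g - sm * g.sum(axis=axis, keepdims=True),
                                 own=True)

        return Tensor._make(out_data, (self,), backward)

    def layer_norm(self, eps: float = 1e-6):
        """Normalize the last axis to zero mean / unit variance (no affine)."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc ** 2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        out_data = xc * inv
        d = self.data.shape[-1]

        def backward(g):
            if self.requires_grad:
                gxhat = g
                mean_g = gxhat.mean(axis=-1, keepdims=True)
                mean_gx = (gxhat * out_data).mean(axis=-1, keepdims=True)
                self._accumulate(inv * (gxhat - mean_g - out_data * mean_gx),
                                 own=True)
            _ = d

        return Tensor._make(out_data, (self,), backward)

    # -- backward pass ----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p._backward is not None or p.requires_grad:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list, axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors: list, axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis), own=True)

    return Tensor._make(out_data, tuple(tensors), backward)
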