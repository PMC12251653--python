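"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: a :class:`Tensor` wraps a float
ndarray (float64 by default; float32 is supported so networks can train at
memory-bandwidth speed), records the operations that produced it, and
:meth:`Tensor.backward`
accumulates gradients by reverse topological traversal.  The op set is exactly
what the spectral networks and distribution-adaptation losses need — elementwise
arithmetic with broadcasting, matmul, ReLU/sigmoid/exp, reductions, reshape,
concatenation, and strided 1-D (depthwise) convolution.  Every op's gradient is
finite-difference checked in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "depthwise_conv1d", "adaptive_avg_pool1d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A float64 array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -----------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _make(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic introspection ------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        if not isinstance(other, Tensor):
            if np.isscalar(other):
                # scalar fast path; also keeps float32 data float32
                c = float(other)

                def backward_s(g, a=self):
                    if a.requires_grad:
                        a._accum(g)

                return self._make(self.data + c, (self,), backward_s)
            other = Tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        if not isinstance(other, Tensor):
            if np.isscalar(other):
                c = float(other)

                def backward_s(g, a=self, c=c):
                    if a.requires_grad:
                        a._accum(g * c)

                return self._make(self.data * c, (self,), backward_s)
            other = Tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("division by a Tensor is not supported; multiply by a reciprocal")
        return self * (1.0 / other)

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def backward(g, a=self, p=float(exponent)):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1.0))

        return self._make(self.data ** float(exponent), (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = g @ b.data.swapaxes(-1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = a.data.swapaxes(-1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    # -- nonlinearities -------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self) -> "Tensor":
        # numerically stable two-sided form (no overflow for large |x|)
        x = self.data
        s = np.empty_like(x)
        pos = x >= 0
        with np.errstate(over="ignore"):
            s[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
            e = np.exp(x[~pos])
        s[~pos] = e / (1.0 + e)

        def backward(g, a=self, s=s):
            if a.requires_grad:
                a._accum(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def exp(self) -> "Tensor":
        # overflow becomes inf; training loops surface non-finite losses
        with np.errstate(over="ignore"):
            e = np.exp(self.data)

        def backward(g, a=self, e=e):
            if a.requires_grad:
                a._accum(g * e)

        return self._make(e, (self,), backward)

    # -- reductions / shape ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            count = int(np.prod([self.data.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g, a=self, old=old):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose2d(self) -> "Tensor":
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.T)

        return self._make(self.data.T, (self,), backward)

    # -- autograd machinery ----------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        self.grad = g if self.grad is None else self.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, iter(self._parents))]
        seen.add(id(self))
        # iterative DFS: deep graphs (many conv layers) must not hit the
        # Python recursion limit
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if id(p) not in seen and p.requires_grad:
                    seen.add(id(p))
                    stack.append((p, iter(p._parents)))
                    advanced = True
                    break
            if not advanced:
                stack.pop()
                topo.append(node)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along an axis."""
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tuple(tensors), axis=axis, offsets=offsets):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    data = np.concatenate([t.data for t in tensors], axis=axis)
    return Tensor._make(data, tensors, backward)


def _conv_windows(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    # (N, C, Lp) -> (N, C, L_out, k); materialised contiguously because the
    # same windows feed one forward and two backward einsums
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
    return np.ascontiguousarray(win[:, :, ::stride, :])


def adaptive_avg_pool1d(x: Tensor, out_len: int) -> Tensor:
    """Average-pool (N, C, L) down to (N, C, out_len).

    Bins are the contiguous partition ``[floor(i*L/P), floor((i+1)*L/P))`` —
    covering, non-overlapping, sizes differing by at most one.
    """
    N, C, L = x.data.shape
    P = out_len
    if L < P:
        raise ValueError(f"cannot pool length {L} up to {P}")
    edges = (np.arange(P + 1) * L) // P
    lo = edges[:-1]
    sizes = np.diff(edges)
    inv = (1.0 / sizes).astype(x.data.dtype)
    binidx = np.repeat(np.arange(P), sizes)
    y = np.add.reduceat(x.data, lo, axis=2) * inv

    def backward(g, x=x, binidx=binidx, inv=inv):
        if x.requires_grad:
            x._accum((g * inv)[:, :, binidx])

    return Tensor._make(y, (x,), backward)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
           padding: int | None = None) -> Tensor:
    """Standard 1-D convolution (cross-correlation).

    ``x``: (N, C_in, L); ``weight``: (C_out, C_in, K); 'same' zero padding by
    default (``padding=None`` means K//2), so stride 1 preserves length.
    """
    N, C_in, L = x.data.shape
    C_out, C_w, K = weight.data.shape
    if C_w != C_in:
        raise ValueError(f"input has {C_in} channels, weight expects {C_w}")
    pad = K // 2 if padding is None else padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    win = _conv_windows(xp, K, stride)  # (N, C_in, L_out, K)
    y = np.einsum("nclk,ock->nol", win, weight.data, optimize=True)
    if bias is not None:
        y = y + bias.data[None, :, None]
    L_out = y.shape[2]

    parents = [x, weight] + ([bias] if bias is not None else [])

    def backward(g, x=x, weight=weight, bias=bias, win=win, stride=stride,
                 pad=pad, K=K, L=L, L_out=L_out):
        if weight.requires_grad:
            weight._accum(np.einsum("nclk,nol->ock", win, g, optimize=True))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            dxp = np.zeros((g.shape[0], weight.data.shape[1], L + 2 * pad),
                           dtype=g.dtype)
            for k in range(K):
                contrib = np.einsum("nol,oc->ncl", g, weight.data[:, :, k], optimize=True)
                dxp[:, :, k : k + stride * L_out : stride] += contrib
            x._accum(dxp[:, :, pad : pad + L] if pad else dxp)

    return Tensor._make(y, parents, backward)


def depthwise_conv1d(x: Tensor, weight: Tensor, bias: Tensor | None,
                     stride: int = 1, padding: int | None = None) -> Tensor:
    """Depthwise 1-D convolution: one kernel per channel.

    ``x``: (N, C, L); ``weight``: (C, K); each channel is convolved with its
    own kernel (the spatial half of a depthwise-separable convolution).
    """
    N, C, L = x.data.shape
    C_w, K = weight.data.shape
    if C_w != C:
        raise ValueError(f"input has {C} channels, depthwise weight expects {C_w}")
    pad = K // 2 if padding is None else padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    win = _conv_windows(xp, K, stride)  # (N, C, L_out, K)
    y = np.einsum("nclk,ck->ncl", win, weight.data, optimize=True)
    if bias is not None:
        y = y + bias.data[None, :, None]
    L_out = y.shape[2]

    parents = [x, weight] + ([bias] if bias is not None else [])

    def backward(g, x=x, weight=weight, bias=bias, win=win, stride=stride,
                 pad=pad, K=K, L=L, L_out=L_out):
        if weight.requires_grad:
            weight._accum(np.einsum("nclk,ncl->ck", win, g, optimize=True))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            dxp = np.zeros((g.shape[0], C, L + 2 * pad), dtype=g.dtype)
            for k in range(K):
                dxp[:, :, k : k + stride * L_out : stride] += g * weight.data[None, :, k, None]
            x._accum(dxp[:, :, pad : pad + L] if pad else dxp)

    return Tensor._make(y, parents, backward)
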