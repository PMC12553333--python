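"""Compact reverse-mode automatic differentiation over NumPy arrays.

Every trainable quantity in the model zoo is a :class:`Tensor`; forward
passes compose the primitives below and ``backward()`` accumulates exact
gradients by walking the tape in reverse topological order.  The primitive
set is deliberately small: dense linear algebra, elementwise nonlinearities,
reductions, 1-D convolution (im2col), and the gather / segment-sum pair that
graph message passing needs.  Dtypes are preserved (float32 models for
speed, float64 wherever tests check closed forms).
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

ArrayLike = "np.ndarray | float | int"


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Tuple["Tensor", ...] = (),
                 backward: Optional[Callable[[np.ndarray], None]] = None):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        # No defensive copy: every backward rule hands a given buffer to at
        # most one parent (aliasing audit in the op definitions), so an
        # in-place += can only ever touch buffers that are already consumed.
        if self.grad is None:
            self.grad = np.asarray(g, dtype=self.data.dtype)
        else:
            self.grad = self.grad + g if not self.grad.flags.writeable \
                else self.grad.__iadd__(g)

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar output")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        if _is_pyscalar(other):
            return add(self, -float(other))
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        if _is_pyscalar(other):
            return add(-self, float(other))
        return add(_wrap(other), -self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if _is_pyscalar(other):
            return mul(self, 1.0 / float(other))
        return mul(self, power(_wrap(other), -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def max(self, axis=None, keepdims=False):
        return tmax(self, axis, keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes or None)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _node(data, parents, backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=tuple(parents),
                  backward=backward if req else None)


# -- primitives -----------------------------------------------------------

def _is_pyscalar(x) -> bool:
    return isinstance(x, (int, float)) or (np.ndim(x) == 0 and
                                           not isinstance(x, Tensor))


def add(a, b) -> Tensor:
    # scalar fast path: Python scalars use weak promotion (dtype preserved)
    if _is_pyscalar(b):
        a = _wrap(a)
        s = float(b)

        def bwd_s(g):
            a._accumulate(g)

        return _node(a.data + s, (a,), bwd_s)
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            gb = _unbroadcast(g, b.shape)
            if a.requires_grad and gb is g:
                gb = g.copy()  # keep the two parent buffers distinct
            b._accumulate(gb)

    return _node(out_data, (a, b), bwd)


def mul(a, b) -> Tensor:
    if _is_pyscalar(b):
        a = _wrap(a)
        s = float(b)

        def bwd_s(g):
            a._accumulate(g * s)

        return _node(a.data * s, (a,), bwd_s)
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _node(out_data, (a, b), bwd)


def power(a, p: float) -> Tensor:
    a = _wrap(a)
    out_data = a.data ** p

    def bwd(g):
        a._accumulate(g * p * a.data ** (p - 1.0))

    return _node(out_data, (a,), bwd)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.shape))

    return _node(out_data, (a, b), bwd)


def exp(a) -> Tensor:
    a = _wrap(a)
    out_data = np.exp(a.data)

    def bwd(g):
        a._accumulate(g * out_data)

    return _node(out_data, (a,), bwd)


def log(a) -> Tensor:
    a = _wrap(a)
    out_data = np.log(a.data)

    def bwd(g):
        a._accumulate(g / a.data)

    return _node(out_data, (a,), bwd)


def tanh(a) -> Tensor:
    a = _wrap(a)
    out_data = np.tanh(a.data)

    def bwd(g):
        a._accumulate(g * (1.0 - out_data ** 2))

    return _node(out_data, (a,), bwd)


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    with np.errstate(over="ignore"):
        out_data = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    return _node(out_data, (a,), bwd)


def relu(a) -> Tensor:
    a = _wrap(a)
    out_data = np.maximum(a.data, 0.0)

    def bwd(g):
        a._accumulate(g * (a.data > 0))

    return _node(out_data, (a,), bwd)


def leaky_relu(a, alpha: float = 0.01) -> Tensor:
    a = _wrap(a)
    out_data = np.where(a.data > 0, a.data, alpha * a.data)

    def bwd(g):
        a._accumulate(g * np.where(a.data > 0, 1.0, alpha))

    return _node(out_data, (a,), bwd)


def tabs(a) -> Tensor:
    a = _wrap(a)
    out_data = np.abs(a.data)

    def bwd(g):
        a._accumulate(g * np.sign(a.data))

    return _node(out_data, (a,), bwd)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, axes)
        a._accumulate(np.broadcast_to(g, a.shape))  # read-only view is fine

    return _node(out_data, (a,), bwd)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def tmax(a, axis=None, keepdims=False) -> Tensor:
    """Max reduction; ties share the gradient equally."""
    a = _wrap(a)
    out_data = a.data.max(axis=axis, keepdims=keepdims)

    def bwd(g):
        full = a.data.max(axis=axis, keepdims=True)
        hit = (a.data == full)
        count = hit.sum(axis=axis, keepdims=True)
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, axes)
        a._accumulate((hit / count) * g)

    return _node(out_data, (a,), bwd)


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    out_data = a.data.reshape(shape)

    def bwd(g):
        a._accumulate(g.reshape(a.shape))

    return _node(out_data, (a,), bwd)


def transpose(a, axes=None) -> Tensor:
    a = _wrap(a)
    out_data = np.transpose(a.data, axes)

    def bwd(g):
        inv = None if axes is None else np.argsort(axes)
        a._accumulate(np.transpose(g, inv))

    return _node(out_data, (a,), bwd)


def getitem(a, idx) -> Tensor:
    a = _wrap(a)
    out_data = a.data[idx]

    def bwd(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a._accumulate(full)

    return _node(out_data, (a,), bwd)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _node(out_data, tuple(tensors), bwd)


def take_rows(a, index: np.ndarray) -> Tensor:
    """Row gather ``a[index]`` (embedding lookup / graph message gather)."""
    a = _wrap(a)
    index = np.asarray(index, dtype=np.int64)
    out_data = a.data[index]

    def bwd(g):
        full = np.zeros_like(a.data)
        np.add.at(full, index, g)
        a._accumulate(full)

    return _node(out_data, (a,), bwd)


def segment_sum(a, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``a`` into ``num_segments`` buckets (scatter-add)."""
    a = _wrap(a)
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    out_shape = (num_segments,) + a.shape[1:]
    out_data = np.zeros(out_shape, dtype=a.dtype)
    np.add.at(out_data, segment_ids, a.data)

    def bwd(g):
        a._accumulate(g[segment_ids])

    return _node(out_data, (a,), bwd)


def segment_max(a, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Per-segment row-wise maximum; gradient routed to (tied) argmaxes."""
    a = _wrap(a)
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    out_shape = (num_segments,) + a.shape[1:]
    out_data = np.full(out_shape, -np.inf, dtype=a.dtype)
    np.maximum.at(out_data, segment_ids, a.data)

    def bwd(g):
        hit = (a.data == out_data[segment_ids])
        count = np.zeros(out_shape, dtype=a.dtype)
        np.add.at(count, segment_ids, hit.astype(a.dtype))
        a._accumulate(hit * (g / np.maximum(count, 1.0))[segment_ids])

    return _node(out_data, (a,), bwd)


def softmax(a, axis: int = -1, mask: Optional[np.ndarray] = None) -> Tensor:
    """Numerically stable softmax (fused); optionally restricted to the
    mask==1 slots, which then sum to 1 while masked slots are exactly 0."""
    a = _wrap(a)
    z = np.array(a.data, copy=True)
    if mask is not None:
        z[mask == 0] = -np.inf
    z -= z.max(axis=axis, keepdims=True)  # rows have >= 1 unmasked slot
    np.exp(z, out=z)
    y = z / z.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        a._accumulate(y * (g - dot))

    return _node(y, (a,), bwd)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = _wrap(a)
    shift = Tensor(a.data.max(axis=axis, keepdims=True))
    z = add(a, mul(shift, -1.0))
    return add(z, mul(log(tsum(exp(z), axis=axis, keepdims=True)), -1.0))


def segment_softmax(scores, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of a score vector within each segment (attention over
    variable-size neighborhoods)."""
    scores = _wrap(scores)
    m = np.full((num_segments,) + scores.shape[1:], -np.inf, dtype=scores.dtype)
    np.maximum.at(m, segment_ids, scores.data)
    shifted = add(scores, Tensor(-m[segment_ids]))  # constant stabilizer
    e = exp(shifted)
    z = segment_sum(e, segment_ids, num_segments)
    return mul(e, power(take_rows(z, segment_ids), -1.0))


def conv1d(x, w, b=None, padding: str = "same") -> Tensor:
    """1-D convolution (cross-correlation) along the length axis.

    x: (B, L, C_in); w: (K, C_in, C_out); b: (C_out,).
    ``same`` keeps the length (zero padding split left/right);
    ``valid`` yields L - K + 1 positions.
    """
    x, w = _wrap(x), _wrap(w)
    B, L, Cin = x.shape
    K, Cin2, Cout = w.shape
    assert Cin == Cin2, f"channel mismatch {Cin} vs {Cin2}"
    if padding == "same":
        left = (K - 1) // 2
        right = K - 1 - left
    elif padding == "valid":
        left = right = 0
    else:
        raise ValueError(f"bad padding {padding!r}")
    Lp = L + left + right
    Lout = Lp - K + 1
    xp = np.zeros((B, Lp, Cin), dtype=x.dtype)
    xp[:, left:left + L, :] = x.data
    s0, s1, s2 = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, shape=(B, Lout, K, Cin), strides=(s0, s1, s1, s2))
    cols2 = np.ascontiguousarray(cols).reshape(B * Lout, K * Cin)
    wf = w.data.reshape(K * Cin, Cout)
    out_data = (cols2 @ wf).reshape(B, Lout, Cout)
    if b is not None:
        out_data = out_data + b.data

    def bwd(g):
        gf = g.reshape(B * Lout, Cout)
        if w.requires_grad:
            w._accumulate((cols2.T @ gf).reshape(K, Cin, Cout))
        if b is not None and b.requires_grad:
            b._accumulate(gf.sum(axis=0))
        if x.requires_grad:
            dcols = (gf @ wf.T).reshape(B, Lout, K, Cin)
            dxp = np.zeros_like(xp)
            for k in range(K):
                dxp[:, k:k + Lout, :] += dcols[:, :, k, :]
            x._accumulate(dxp[:, left:left + L, :])

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, bwd)


def dropout(a, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only in training mode."""
    if rate <= 0.0:
        return _wrap(a)
    a = _wrap(a)
    keep = (rng.random(a.shape) >= rate).astype(a.dtype) / (1.0 - rate)
    return mul(a, Tensor(keep))
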