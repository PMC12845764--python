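"""Compact reverse-mode automatic differentiation over numpy arrays.

The adversarial training loop needs parameter gradients of a penalty
that is itself a function of an input gradient (the WGAN-GP term), i.e.
double backpropagation.  Every vector-Jacobian product here is
expressed in terms of the same differentiable ops, so calling
:func:`grad` with ``create_graph=True`` yields gradient tensors that
can be differentiated again.

Only the operations the generator/critic architectures require are
provided: broadcast arithmetic, 2-D matmul, reshape/transpose,
gather/scatter on the last axis (convolutions are lowered to these),
tanh / leaky-relu, reductions, sqrt/pow.
"""

from __future__ import annotations

import numpy as np

_GRAD_ENABLED = [True]
_DTYPE = [np.float32]


def set_dtype(dtype) -> None:
    """Set the engine's working dtype (float32 default; float64 for
    high-precision checks such as finite-difference comparisons)."""
    _DTYPE[0] = np.dtype(dtype).type


def get_dtype():
    return _DTYPE[0]


class double_precision:
    """Context manager: run the engine in float64."""

    def __enter__(self):
        self.prev = _DTYPE[0]
        _DTYPE[0] = np.float64
        return self

    def __exit__(self, *exc):
        _DTYPE[0] = self.prev
        return False


class no_grad:
    """Context manager: ops inside build no graph (constants out)."""

    def __enter__(self):
        self.prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self.prev
        return False


class enable_grad:
    def __enter__(self):
        self.prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = True
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self.prev
        return False


class Tensor:
    __slots__ = ("data", "requires_grad", "parents")

    def __init__(self, data, requires_grad: bool = False, parents=None):
        self.data = np.asarray(data, dtype=_DTYPE[0])
        self.requires_grad = bool(requires_grad)
        self.parents = parents or []  # [(Tensor, vjp_fn), ...]

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        return mul(self, power(other, -1.0))

    def __pow__(self, c):
        return power(self, c)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents) -> Tensor:
    """Build an op output; parents are pruned when grad is disabled."""
    if _GRAD_ENABLED[0]:
        parents = [(p, fn) for p, fn in parents if p.requires_grad]
        return Tensor(data, requires_grad=bool(parents), parents=parents)
    return Tensor(data)


# ---------------------------------------------------------------------------
# broadcasting helpers


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.data.shape == shape:
        return g
    ndiff = g.data.ndim - len(shape)
    if ndiff > 0:
        g = tsum(g, axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.data.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.data.shape != shape:
        g = reshape(g, shape)
    return g


def broadcast_to(a: Tensor, shape) -> Tensor:
    out = np.broadcast_to(a.data, shape)
    return _make(out, [(a, lambda g, sh=a.data.shape: _unbroadcast(g, sh))])


# ---------------------------------------------------------------------------
# arithmetic


def add(a: Tensor, b: Tensor) -> Tensor:
    return _make(
        a.data + b.data,
        [
            (a, lambda g, sh=a.data.shape: _unbroadcast(g, sh)),
            (b, lambda g, sh=b.data.shape: _unbroadcast(g, sh)),
        ],
    )


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _make(
        a.data * b.data,
        [
            (a, lambda g: _unbroadcast(mul(g, b), a.data.shape)),
            (b, lambda g: _unbroadcast(mul(g, a), b.data.shape)),
        ],
    )


def power(a: Tensor, c: float) -> Tensor:
    out = a.data**c
    return _make(out, [(a, lambda g: mul(g, mul(Tensor(float(c)), power(a, c - 1.0))))])


def sqrt(a: Tensor, eps: float = 0.0) -> Tensor:
    """Elementwise sqrt; ``eps`` guards the derivative at zero."""
    if eps:
        a = add(a, Tensor(float(eps)))
    return power(a, 0.5)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D matrix product (M,K)@(K,N)."""
    if a.data.ndim != 2 or b.data.ndim != 2:
        raise ValueError("matmul supports 2-D operands only; reshape first")
    return _make(
        a.data @ b.data,
        [
            (a, lambda g: matmul(g, transpose(b, (1, 0)))),
            (b, lambda g: matmul(transpose(a, (1, 0)), g)),
        ],
    )


def reshape(a: Tensor, shape) -> Tensor:
    return _make(a.data.reshape(shape), [(a, lambda g, sh=a.data.shape: reshape(g, sh))])


def transpose(a: Tensor, axes) -> Tensor:
    inv = tuple(np.argsort(axes))
    return _make(a.data.transpose(axes), [(a, lambda g: transpose(g, inv))])


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = a.data.sum(axis=axis, keepdims=keepdims)
    in_shape = a.data.shape

    if axis is None:
        kd_shape = (1,) * a.data.ndim
    else:
        ax = (axis,) if isinstance(axis, int) else tuple(axis)
        ax = tuple(x % a.data.ndim for x in ax)
        kd_shape = tuple(1 if i in ax else s for i, s in enumerate(in_shape))

    def vjp(g):
        return broadcast_to(reshape(g, kd_shape), in_shape)

    return _make(out, [(a, vjp)])


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[i] for i in np.atleast_1d(axis)]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(1.0 / float(n)))


# ---------------------------------------------------------------------------
# nonlinearities


def tanh(a: Tensor) -> Tensor:
    ydata = np.tanh(a.data)
    out = _make(ydata, [])
    if _GRAD_ENABLED[0] and a.requires_grad:
        # vjp uses the output node so the second derivative flows through it
        out.requires_grad = True
        out.parents = [(a, lambda g: mul(g, add(Tensor(1.0), -power(out, 2.0))))]
    return out


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    mask = np.where(a.data > 0, 1.0, slope)
    return _make(a.data * mask, [(a, lambda g: mul(g, Tensor(mask)))])


def relu(a: Tensor) -> Tensor:
    return leaky_relu(a, 0.0)


# ---------------------------------------------------------------------------
# gather / scatter on the last axis (convolution plumbing)


def gather_last(a: Tensor, idx: np.ndarray) -> Tensor:
    """``out[..., *idx.shape] = a[..., idx]`` (outer indexing, repeats allowed)."""
    idx = np.asarray(idx)
    out = a.data[..., idx]
    size = a.data.shape[-1]
    return _make(out, [(a, lambda g: scatter_add_last(g, idx, size))])


def scatter_add_last(g: Tensor, idx: np.ndarray, size: int) -> Tensor:
    """Adjoint of :func:`gather_last`; sums duplicate indices."""
    idx = np.asarray(idx)
    lead = g.data.shape[: g.data.ndim - idx.ndim]
    out = np.zeros(lead + (size,), dtype=_DTYPE[0])
    np.add.at(out, (Ellipsis,) + (idx,), g.data)
    return _make(out, [(g, lambda gg: gather_last(gg, idx))])


def scatter_last(a: Tensor, idx: np.ndarray, size: int) -> Tensor:
    """Place ``a``'s last axis at distinct positions ``idx`` in a zero array."""
    idx = np.asarray(idx)
    out = np.zeros(a.data.shape[:-1] + (size,), dtype=_DTYPE[0])
    out[..., idx] = a.data
    return _make(out, [(a, lambda g: gather_last(g, idx))])


def shuffle_last(a: Tensor, idx: np.ndarray, inv_idx: np.ndarray) -> Tensor:
    """Per-row permutation of the last axis (take_along_axis semantics).

    ``idx`` and ``inv_idx`` must be mutually inverse permutations along
    the last axis, broadcastable against ``a`` (e.g. shape (B, 1, L) for
    per-batch-item circular shifts).
    """
    out = np.take_along_axis(a.data, np.broadcast_to(idx, a.data.shape), axis=-1)
    return _make(out, [(a, lambda g: shuffle_last(g, inv_idx, idx))])


def im2col(a: Tensor, K: int, stride: int) -> Tensor:
    """Sliding windows of the last axis: (..., L) -> (..., L_out, K).

    The adjoint (:func:`col2im`) is the overlap-add "fold"; both are
    linear, so the pair is double-backprop safe and avoids the slow
    generic scatter path in convolution backward passes.
    """
    L = a.data.shape[-1]
    view = np.lib.stride_tricks.sliding_window_view(a.data, K, axis=-1)[..., ::stride, :]
    out = np.ascontiguousarray(view)
    return _make(out, [(a, lambda g: col2im(g, K, stride, L))])


def col2im(g: Tensor, K: int, stride: int, L: int) -> Tensor:
    """Overlap-add fold: (..., L_out, K) -> (..., L); adjoint of im2col."""
    L_out = g.data.shape[-2]
    out = np.zeros(g.data.shape[:-2] + (L,), dtype=_DTYPE[0])
    for k in range(K):
        out[..., k : k + stride * L_out : stride] += g.data[..., :, k]
    return _make(out, [(g, lambda gg: im2col(gg, K, stride))])


def im2col_mat(a: Tensor, K: int, stride: int) -> Tensor:
    """Convolution patches in matmul layout: (B, C, L) -> (B, L_out, C*K).

    Fuses the window extraction and the (B, L_out, C, K) transpose into
    one copy; the adjoint folds back with :func:`col2im`.
    """
    B, C, L = a.data.shape
    view = np.lib.stride_tricks.sliding_window_view(a.data, K, axis=-1)[..., ::stride, :]
    L_out = view.shape[-2]
    out = view.transpose(0, 2, 1, 3).reshape(B, L_out, C * K)

    def vjp(g):
        g4 = transpose(reshape(g, (B, L_out, C, K)), (0, 2, 1, 3))
        return col2im(g4, K, stride, L)

    return _make(out, [(a, vjp)])


def pad_last(a: Tensor, left: int, right: int) -> Tensor:
    width = [(0, 0)] * (a.data.ndim - 1) + [(left, right)]
    out = np.pad(a.data, width)
    L = a.data.shape[-1]
    return _make(out, [(a, lambda g: slice_last(g, left, left + L))])


def slice_last(a: Tensor, start: int, stop: int) -> Tensor:
    out = a.data[..., start:stop]
    L = a.data.shape[-1]
    return _make(out, [(a, lambda g: pad_last(g, start, L - stop))])


# ---------------------------------------------------------------------------
# backward


def _topo(output: Tensor) -> list:
    order, seen, stack = [], set(), [(output, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node.parents:
            stack.append((parent, False))
    return order


def grad(output: Tensor, inputs, grad_output=None, create_graph: bool = False) -> list:
    """Gradients of a scalar ``output`` w.r.t. ``inputs``.

    With ``create_graph=True`` the returned tensors carry their own
    graph and can be differentiated again (double backprop).
    """
    if output.data.size != 1:
        raise ValueError("grad expects a scalar output")
    seed = grad_output if grad_output is not None else Tensor(np.ones_like(output.data))
    order = _topo(output)
    grads: dict[int, Tensor] = {id(output): seed}
    final: dict[int, Tensor] = {}
    ctx = enable_grad() if create_graph else no_grad()
    with ctx:
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            final[id(node)] = g
            for parent, vjp in node.parents:
                pg = vjp(g)
                if id(parent) in grads:
                    grads[id(parent)] = add(grads[id(parent)], pg)
                else:
                    grads[id(parent)] = pg
    out = []
    for inp in inputs:
        out.append(final.get(id(inp), Tensor(np.zeros_like(inp.data))))
    return out
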