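"""Minimal reverse-mode autodiff on numpy arrays.

The toolkit exists to train the volumetric motion-estimation networks on a
plain CPU numpy backend.  It implements exactly the operations those
architectures need (N-dimensional convolution, average pooling, global
average pooling, dense layers, ReLU, concatenation/stacking and the squared
error reductions of the training loss) as nodes of a dynamically built tape.

Tensors wrap ``numpy`` arrays; operations return new tensors holding a
closure that maps the output gradient to the parents' gradients.  Calling
:meth:`Tensor.backward` on a scalar loss walks the tape in reverse
topological order and accumulates ``.grad`` on every tensor that requires
gradients (parameters are tensors with ``requires_grad=True``).  Gradients
are plain numpy arrays, never tensors, so no higher-order graphs are built.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Tuple

import numpy as np

from . import functional as F

__all__ = [
    "Tensor",
    "no_grad",
    "grad_enabled",
    "as_tensor",
    "add",
    "scale",
    "relu",
    "reshape",
    "moveaxis",
    "concat",
    "stack",
    "linear",
    "conv",
    "avg_pool",
    "global_mean",
    "instance_norm",
    "mean_squared_norm",
]


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode).

    Inside the context no tensor records parents or backward closures, so
    forward passes neither retain activations nor hold convolution buffer
    caches.  Parameters keep ``requires_grad=True``; only new graph edges
    are suppressed.
    """

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """A node in the computation graph wrapping an ``ndarray``."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Tuple["Tensor", ...] = (),
        backward: Optional[Callable[[np.ndarray], Sequence[Optional[np.ndarray]]]] = None,
    ):
        self.data = np.asarray(data)
        if parents and not _GRAD_ENABLED:
            parents = ()
            backward = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self.grad: Optional[np.ndarray] = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every upstream tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar tensor")
            grad = np.ones_like(self.data)

        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep for long tapes
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.grad is None:
                node.grad = g.copy()
            else:
                node.grad = node.grad + g
            if node._backward is None:
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise sum of two same-shaped tensors."""
    if a.shape != b.shape:
        raise ValueError(f"add: shape mismatch {a.shape} vs {b.shape}")
    return Tensor(a.data + b.data, parents=(a, b), backward=lambda g: (g, g))


def scale(x: Tensor, c: float) -> Tensor:
    """Multiply by a python scalar."""
    c = float(c)
    return Tensor(x.data * c, parents=(x,), backward=lambda g: (g * c,))


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(
        np.where(mask, x.data, 0.0).astype(x.dtype, copy=False),
        parents=(x,),
        backward=lambda g: (np.where(mask, g, 0.0),),
    )


def leaky_relu(x: Tensor, slope: float = 0.1) -> Tensor:
    mask = x.data > 0
    return Tensor(
        np.where(mask, x.data, slope * x.data).astype(x.dtype, copy=False),
        parents=(x,),
        backward=lambda g: (np.where(mask, g, slope * g),),
    )


def reshape(x: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    orig = x.shape
    return Tensor(x.data.reshape(shape), parents=(x,),
                  backward=lambda g: (g.reshape(orig),))


def moveaxis(x: Tensor, src: int, dst: int) -> Tensor:
    return Tensor(np.moveaxis(x.data, src, dst), parents=(x,),
                  backward=lambda g: (np.moveaxis(g, dst, src),))


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors), backward=bwd)


def stack(tensors: Sequence[Tensor], axis: int) -> Tensor:
    def bwd(g):
        moved = np.moveaxis(g, axis, 0)
        return tuple(moved[i] for i in range(len(tensors)))

    return Tensor(np.stack([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=bwd)


# ---------------------------------------------------------------------------
# dense / conv / pooling
# ---------------------------------------------------------------------------

def linear(x: Tensor, w: Tensor, b: Optional[Tensor] = None) -> Tensor:
    """``x @ w + b`` with ``x`` of shape (N, F) and ``w`` of shape (F, O)."""
    y = x.data @ w.data
    if b is not None:
        y = y + b.data

    def bwd(g):
        dx = g @ w.data.T if x.requires_grad else None
        dw = x.data.T @ g if w.requires_grad else None
        db = g.sum(axis=0) if (b is not None and b.requires_grad) else None
        return (dx, dw, db) if b is not None else (dx, dw)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(y, parents=parents, backward=bwd)


def conv(x: Tensor, w: Tensor, b: Optional[Tensor],
         pads: Sequence[Tuple[int, int]],
         strides: Optional[Sequence[int]] = None) -> Tensor:
    """N-dimensional cross-correlation (channels-last).

    ``x``: (N, *spatial, C_in); ``w``: (*kernel, C_in, C_out).  The number of
    convolved axes is inferred from the kernel; 3 gives an ordinary volumetric
    convolution, 4 the spatio-temporal one.
    """
    nd = w.ndim - 2
    strides = tuple(strides) if strides is not None else (1,) * nd
    needs_grad = _GRAD_ENABLED and (
        x.requires_grad or w.requires_grad
        or (b is not None and b.requires_grad))
    if needs_grad:
        y, cache = F.correlate_nd(x.data, w.data, pads, strides,
                                  return_cache=True)
    else:
        y, cache = F.correlate_nd(x.data, w.data, pads, strides), None
    if b is not None:
        y = y + b.data

    def bwd(g):
        dx, dw = F.correlate_nd_backward(
            x.data, w.data, g, pads, strides,
            need_dx=x.requires_grad, need_dw=w.requires_grad, cache=cache,
        )
        F.release_cache(cache)
        db = None
        if b is not None and b.requires_grad:
            db = g.sum(axis=tuple(range(g.ndim - 1)))
        return (dx, dw, db) if b is not None else (dx, dw)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(y, parents=parents, backward=bwd)


def avg_pool(x: Tensor, axes: Sequence[int], factors: Sequence[int]) -> Tensor:
    """Non-overlapping average pooling along ``axes`` with ceil semantics.

    Sizes that are not multiples of the factor keep a trailing partial window
    averaged over its actual elements, so a temporal axis of length 5 pools to
    3 and eventually clamps at 1 instead of losing frames.
    """
    data = x.data
    meta = []
    for ax, f in zip(axes, factors):
        n = data.shape[ax]
        if f <= 1 or n <= 1:
            continue
        idx = np.arange(0, n, f)
        counts = np.diff(np.append(idx, n)).astype(data.dtype)
        shape = [1] * data.ndim
        shape[ax] = len(idx)
        data = np.add.reduceat(data, idx, axis=ax) / counts.reshape(shape)
        meta.append((ax, counts))

    def bwd(g):
        for ax, counts in reversed(meta):
            shape = [1] * g.ndim
            shape[ax] = len(counts)
            g = np.repeat(g / counts.reshape(shape), counts.astype(int), axis=ax)
        return (g,)

    return Tensor(data, parents=(x,), backward=bwd)


def global_mean(x: Tensor, axes: Sequence[int]) -> Tensor:
    """Mean over ``axes`` (dropped from the output) — global average pooling."""
    axes = tuple(sorted(axes))
    count = float(np.prod([x.shape[a] for a in axes]))
    y = x.data.mean(axis=axes)

    def bwd(g):
        ge = np.expand_dims(g, axes)
        return (np.broadcast_to(ge / count, x.shape).astype(g.dtype, copy=False),)

    return Tensor(y, parents=(x,), backward=bwd)


def instance_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel standardization over all interior axes.

    Channels-last: normalizes each (sample, channel) slab over the spatial
    (and temporal) axes, then applies a learned per-channel gain and bias.
    Statistics are recomputed at evaluation time, so the op is deterministic
    and needs no running averages.
    """
    axes = tuple(range(1, x.ndim - 1))
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    y = gain.data * xhat + bias.data
    m = float(np.prod([x.shape[a] for a in axes]))

    def bwd(g):
        dg = (g * xhat).sum(axis=tuple(range(x.ndim - 1))) if gain.requires_grad else None
        db = g.sum(axis=tuple(range(x.ndim - 1))) if bias.requires_grad else None
        dx = None
        if x.requires_grad:
            gx = g * gain.data
            dx = inv * (gx - gx.mean(axis=axes, keepdims=True)
                        - xhat * (gx * xhat).mean(axis=axes, keepdims=True))
            dx = dx.astype(x.dtype, copy=False)
        return (dx, dg, db)

    return Tensor(y.astype(x.dtype, copy=False), parents=(x, gain, bias), backward=bwd)


def mean_squared_norm(pred: Tensor, target: np.ndarray) -> Tensor:
    """``mean_j ||target_j - pred_j||^2`` over the batch axis (axis 0)."""
    target = np.asarray(target, dtype=pred.dtype)
    if target.shape != pred.shape:
        raise ValueError(f"target shape {target.shape} != prediction {pred.shape}")
    d = pred.data - target
    n = pred.shape[0]
    val = float((d * d).sum()) / n

    def bwd(g):
        return (g * (2.0 / n) * d,)

    return Tensor(np.asarray(val, dtype=pred.dtype), parents=(pred,), backward=bwd)
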