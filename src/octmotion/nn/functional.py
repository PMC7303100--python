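"""Raw N-dimensional correlation kernels (forward and backward).

Channels-last layout throughout: inputs are ``(N, *spatial, C_in)``, kernels
``(*K, C_in, C_out)``.  The same code path serves 3D (volumetric) and 4D
(spatio-temporal) convolution; the contraction is lowered to an explicit
im2col + GEMM with per-kernel-offset slice copies, falling back to
batch-chunked evaluation when the column matrix would be very large.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np


def same_pads(kernel: Sequence[int]) -> Tuple[Tuple[int, int], ...]:
    """Zero-padding that keeps stride-1 output sizes equal to the input.

    Odd kernels pad symmetrically; even kernels pad one extra element at the
    trailing edge (relevant for the temporal kernel of size 2).
    """
    return tuple(((k - 1) // 2, k - 1 - (k - 1) // 2) for k in kernel)


def _pad(x: np.ndarray, pads: Sequence[Tuple[int, int]]) -> np.ndarray:
    if all(lo == 0 and hi == 0 for lo, hi in pads):
        return x
    return np.pad(x, [(0, 0), *pads, (0, 0)])


def _offset_slices(kernel: Tuple[int, ...], out_sp: Tuple[int, ...],
                   strides: Tuple[int, ...]):
    """One slice tuple per kernel offset, aligned with the output grid."""
    import itertools

    nd = len(kernel)
    for q in itertools.product(*(range(k) for k in kernel)):
        yield q, (slice(None),) + tuple(
            slice(q[i], q[i] + (out_sp[i] - 1) * strides[i] + 1, strides[i])
            for i in range(nd))


try:  # optional JIT kernels for the bandwidth-bound gather/scatter loops
    from numba import njit as _njit

    @_njit(cache=True)
    def _im2col3_nb(xp, col, sx, sy, sz):
        n, ox, oy, oz, k1, k2, k3, c = col.shape
        for i in range(n):
            for a in range(ox):
                for b in range(oy):
                    for d in range(oz):
                        for q1 in range(k1):
                            for q2 in range(k2):
                                for q3 in range(k3):
                                    src = xp[i, a * sx + q1, b * sy + q2,
                                             d * sz + q3]
                                    dst = col[i, a, b, d, q1, q2, q3]
                                    for e in range(c):
                                        dst[e] = src[e]

    @_njit(cache=True)
    def _im2col4_nb(xp, col, st, sx, sy, sz):
        n, ot, ox, oy, oz, k0, k1, k2, k3, c = col.shape
        for i in range(n):
            for t in range(ot):
                for a in range(ox):
                    for b in range(oy):
                        for d in range(oz):
                            for q0 in range(k0):
                                for q1 in range(k1):
                                    for q2 in range(k2):
                                        for q3 in range(k3):
                                            src = xp[i, t * st + q0,
                                                     a * sx + q1,
                                                     b * sy + q2,
                                                     d * sz + q3]
                                            dst = col[i, t, a, b, d,
                                                      q0, q1, q2, q3]
                                            for e in range(c):
                                                dst[e] = src[e]

    @_njit(cache=True)
    def _scatter3_nb(dxp, dycol, sx, sy, sz):
        n, ox, oy, oz, k1, k2, k3, c = dycol.shape
        for i in range(n):
            for a in range(ox):
                for b in range(oy):
                    for d in range(oz):
                        for q1 in range(k1):
                            for q2 in range(k2):
                                for q3 in range(k3):
                                    dst = dxp[i, a * sx + q1, b * sy + q2,
                                              d * sz + q3]
                                    src = dycol[i, a, b, d, q1, q2, q3]
                                    for e in range(c):
                                        dst[e] += src[e]

    @_njit(cache=True)
    def _scatter4_nb(dxp, dycol, st, sx, sy, sz):
        n, ot, ox, oy, oz, k0, k1, k2, k3, c = dycol.shape
        for i in range(n):
            for t in range(ot):
                for a in range(ox):
                    for b in range(oy):
                        for d in range(oz):
                            for q0 in range(k0):
                                for q1 in range(k1):
                                    for q2 in range(k2):
                                        for q3 in range(k3):
                                            dst = dxp[i, t * st + q0,
                                                      a * sx + q1,
                                                      b * sy + q2,
                                                      d * sz + q3]
                                            src = dycol[i, t, a, b, d,
                                                        q0, q1, q2, q3]
                                            for e in range(c):
                                                dst[e] += src[e]

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba always present in practice
    _HAVE_NUMBA = False


def _im2col(xp: np.ndarray, kernel: Tuple[int, ...],
            out_sp: Tuple[int, ...], strides: Tuple[int, ...]) -> np.ndarray:
    """Materialize the column matrix (N*P, K*C_in)."""
    n = xp.shape[0]
    c_in = xp.shape[-1]
    nk = int(np.prod(kernel))
    npos = int(np.prod(out_sp))
    col = _POOL.acquire((n, *out_sp, *kernel, c_in), xp.dtype)
    if _HAVE_NUMBA and len(kernel) == 3 and xp.flags.c_contiguous:
        _im2col3_nb(xp, col, *strides)
    elif _HAVE_NUMBA and len(kernel) == 4 and xp.flags.c_contiguous:
        _im2col4_nb(xp, col, *strides)
    else:
        colq = col.reshape(n, *out_sp, nk, c_in)
        for qi, (q, sel) in enumerate(_offset_slices(kernel, out_sp, strides)):
            colq[..., qi, :] = xp[sel]
    return col.reshape(n * npos, nk * c_in)


def _scatter_add(dxp: np.ndarray, dycol: np.ndarray,
                 kernel: Tuple[int, ...], out_sp: Tuple[int, ...],
                 strides: Tuple[int, ...]) -> None:
    """Accumulate column-layout gradients back onto the padded input."""
    n = dxp.shape[0]
    c_in = dxp.shape[-1]
    shaped = dycol.reshape(n, *out_sp, *kernel, c_in)
    if _HAVE_NUMBA and len(kernel) == 3:
        _scatter3_nb(dxp, np.ascontiguousarray(shaped), *strides)
    elif _HAVE_NUMBA and len(kernel) == 4:
        _scatter4_nb(dxp, np.ascontiguousarray(shaped), *strides)
    else:
        nk = int(np.prod(kernel))
        shaped_q = shaped.reshape(n, *out_sp, nk, c_in)
        for qi, (q, sel) in enumerate(_offset_slices(kernel, out_sp, strides)):
            dxp[sel] += shaped_q[..., qi, :]


def _conv_shapes(x: np.ndarray, w: np.ndarray,
                 pads: Sequence[Tuple[int, int]],
                 strides: Optional[Sequence[int]]):
    nd = w.ndim - 2
    kernel = w.shape[:nd]
    c_in = w.shape[nd]
    if x.ndim != nd + 2 or x.shape[-1] != c_in:
        raise ValueError(
            f"input shape {x.shape} incompatible with kernel {w.shape}")
    strides = tuple(strides) if strides is not None else (1,) * nd
    out_sp = []
    for i in range(nd):
        padded = x.shape[1 + i] + pads[i][0] + pads[i][1]
        if padded < kernel[i]:
            raise ValueError(
                f"spatial axis {i} of size {padded} (padded) smaller than "
                f"kernel {kernel[i]}")
        out_sp.append((padded - kernel[i]) // strides[i] + 1)
    return kernel, strides, tuple(out_sp)


# columns larger than this are rebuilt in the backward pass instead of cached
_CACHE_BYTES = 1 << 29


class _BufferPool:
    """Reuse large transient buffers across convolution calls.

    Conv shapes repeat every training step; recycling the padded-input,
    column and gradient buffers avoids repeated multi-megabyte mmap/munmap
    cycles, whose page-fault cost otherwise dominates CPU training.
    """

    def __init__(self, per_key: int = 4):
        self._store = {}
        self._per_key = per_key

    def acquire(self, shape, dtype) -> np.ndarray:
        key = (tuple(shape), np.dtype(dtype).str)
        lst = self._store.get(key)
        if lst:
            return lst.pop()
        return np.empty(shape, dtype)

    def release(self, arr: Optional[np.ndarray]) -> None:
        if arr is None or not arr.flags.owndata:
            return
        key = (arr.shape, arr.dtype.str)
        lst = self._store.setdefault(key, [])
        if len(lst) < self._per_key:
            lst.append(arr)


_POOL = _BufferPool()


def _pad_pooled(x: np.ndarray, pads) -> np.ndarray:
    if all(lo == 0 and hi == 0 for lo, hi in pads):
        return x
    shape = (x.shape[0],) + tuple(
        x.shape[1 + i] + lo + hi for i, (lo, hi) in enumerate(pads)
    ) + (x.shape[-1],)
    xp = _POOL.acquire(shape, x.dtype)
    xp[...] = 0.0
    interior = (slice(None),) + tuple(
        slice(lo, lo + x.shape[1 + i]) for i, (lo, hi) in enumerate(pads)
    ) + (slice(None),)
    xp[interior] = x
    return xp


def release_cache(cache) -> None:
    """Return a forward cache's buffers to the pool (end of backward)."""
    if cache is None:
        return
    xp, col = cache
    _POOL.release(xp)
    if col is not None:
        _POOL.release(col.base if col.base is not None else col)


def correlate_nd(x: np.ndarray, w: np.ndarray,
                 pads: Sequence[Tuple[int, int]],
                 strides: Optional[Sequence[int]] = None,
                 return_cache: bool = False):
    """Cross-correlate ``x`` with kernel ``w``.

    ``y[n, p, o] = sum_{q, c} x_padded[n, p*s + q, c] * w[q, c, o]`` with
    multi-indices ``p`` (output position) and ``q`` (kernel offset).
    Lowered to an explicit im2col + GEMM; with ``return_cache`` the column
    matrix (or the padded input, when the column would be very large) is
    returned for reuse by :func:`correlate_nd_backward`.
    """
    nd = w.ndim - 2
    kernel, strides, out_sp = _conv_shapes(x, w, pads, strides)
    c_in, c_out = w.shape[nd], w.shape[nd + 1]
    n = x.shape[0]
    npos = int(np.prod(out_sp))
    xp = _pad_pooled(x, pads)
    col_bytes = n * npos * int(np.prod(kernel)) * c_in * x.itemsize
    if col_bytes <= _CACHE_BYTES:
        col = _im2col(xp, kernel, out_sp, strides)
        y = (col @ w.reshape(-1, c_out)).reshape(n, *out_sp, c_out)
        if return_cache:
            return y, (xp if xp is not x else None, col)
        _POOL.release(xp if xp is not x else None)
        _POOL.release(col.base if col.base is not None else col)
        return y
    # very large instance: chunk over the batch, never materialize fully
    y = np.empty((n, *out_sp, c_out), dtype=x.dtype)
    step = max(1, n // max(1, col_bytes // _CACHE_BYTES + 1))
    for i in range(0, n, step):
        col = _im2col(xp[i:i + step], kernel, out_sp, strides)
        y[i:i + step] = (col @ w.reshape(-1, c_out)).reshape(
            -1, *out_sp, c_out)
    if return_cache:
        return y, (xp, None)
    return y


def correlate_nd_backward(x: np.ndarray, w: np.ndarray, dy: np.ndarray,
                          pads: Sequence[Tuple[int, int]],
                          strides: Optional[Sequence[int]] = None,
                          need_dx: bool = True, need_dw: bool = True,
                          cache=None,
                          ) -> Tuple[Optional[np.ndarray], Optional[np.ndarray]]:
    """Gradients of :func:`correlate_nd` w.r.t. input and kernel.

    With the forward ``cache`` the kernel gradient is a single GEMM against
    the stored column matrix; otherwise the columns are rebuilt per kernel
    offset.  The input gradient is one GEMM against the kernel followed by
    per-offset scatter-adds onto the padded-input grid.
    """
    nd = w.ndim - 2
    kernel, strides, out_sp = _conv_shapes(x, w, pads, strides)
    c_in, c_out = w.shape[nd], w.shape[nd + 1]
    n = x.shape[0]
    npos = int(np.prod(out_sp))
    nk = int(np.prod(kernel))
    dx = dw = None

    if cache is not None:
        xp, col = cache
        if xp is None:
            xp = x
    else:
        xp, col = _pad(x, pads), None
    dy_mat = dy.reshape(-1, c_out)

    if need_dw:
        if col is None:
            col_bytes = n * npos * nk * c_in * x.itemsize
            if col_bytes <= _CACHE_BYTES:
                col = _im2col(xp, kernel, out_sp, strides)
        if col is not None:
            dw = (col.T @ dy_mat).reshape(*kernel, c_in, c_out)
        else:  # very large instance: per-offset accumulation
            dw = np.empty(w.shape, dtype=w.dtype)
            for q, sel in _offset_slices(kernel, out_sp, strides):
                xs = np.ascontiguousarray(xp[sel]).reshape(-1, c_in)
                dw[q] = xs.T @ dy_mat

    if need_dx:
        dxp = _POOL.acquire(xp.shape, x.dtype)
        dxp[...] = 0.0
        if n * npos * nk * c_in * x.itemsize <= _CACHE_BYTES:
            dycol = _POOL.acquire((n * npos, nk * c_in), x.dtype)
            np.matmul(dy_mat, w.reshape(-1, c_out).T, out=dycol)
            _scatter_add(dxp, dycol, kernel, out_sp, strides)
            _POOL.release(dycol)
        else:  # very large instance: per-offset GEMMs
            for q, sel in _offset_slices(kernel, out_sp, strides):
                dxp[sel] += (dy_mat @ w[q].reshape(c_in, c_out).T
                             ).reshape(n, *out_sp, c_in)
        crop = (slice(None),) + tuple(
            slice(pads[i][0], pads[i][0] + x.shape[1 + i]) for i in range(nd))
        dx = np.ascontiguousarray(dxp[crop])
        _POOL.release(dxp)

    return dx, dw
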