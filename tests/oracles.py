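"""Independent brute-force oracles used by the test suite.

These implementations are deliberately naive (nested python loops, explicit
enumeration) and share no code with the package internals they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def conv4d_nested_sum(x: np.ndarray, w: np.ndarray,
                      bias: np.ndarray | None = None,
                      pads=None) -> np.ndarray:
    """Six-nested-loop 4D correlation of (T, X, Y, Z, C) with
    (kt, kx, ky, kz, C_in, C_out)."""
    kt, kx, ky, kz, cin, cout = w.shape
    if pads is not None:
        x = np.pad(x, [*pads, (0, 0)])
    ot = x.shape[0] - kt + 1
    ox = x.shape[1] - kx + 1
    oy = x.shape[2] - ky + 1
    oz = x.shape[3] - kz + 1
    y = np.zeros((ot, ox, oy, oz, cout))
    for t, i, j, k in itertools.product(range(ot), range(ox), range(oy), range(oz)):
        for o in range(cout):
            acc = 0.0
            for dt, di, dj, dk, c in itertools.product(
                    range(kt), range(kx), range(ky), range(kz), range(cin)):
                acc += x[t + dt, i + di, j + dj, k + dk, c] * w[dt, di, dj, dk, c, o]
            y[t, i, j, k, o] = acc + (bias[o] if bias is not None else 0.0)
    return y


def signed_rank_exact_p(diffs: np.ndarray) -> float:
    """Two-sided exact p-value of the Wilcoxon signed-rank statistic by full
    enumeration of sign assignments (feasible for n <= 20 via dynamic
    programming over the rank-sum distribution; no ties assumed)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_plus = int(ranks[d > 0].sum())
    total = n * (n + 1) // 2
    # distribution of W+ under H0: each rank independently + with prob 1/2
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    counts /= 2.0 ** n
    lo = min(w_plus, total - w_plus)
    p = counts[:lo + 1].sum() + counts[total - lo:].sum()
    return float(min(1.0, p))


def pearson_naive(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / math.sqrt((am ** 2).sum() * (bm ** 2).sum()))
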