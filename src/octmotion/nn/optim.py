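"""Adam optimizer."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import Tensor


class Adam:
    """Standard Adam (Kingma & Ba) with bias-corrected moment estimates.

    Moment accumulators and the update arithmetic are kept in float64 even
    for float32 parameters: the second-moment terms span many orders of
    magnitude and single-precision accumulation measurably degrades the
    deeper spatio-temporal models.  Parameters keep their own dtype.
    """

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.t = 0
        self.m = [np.zeros(p.data.shape, dtype=np.float64) for p in self.params]
        self.v = [np.zeros(p.data.shape, dtype=np.float64) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64, copy=False)
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * (g * g)
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            new = p.data.astype(np.float64) - self.lr * mhat / (np.sqrt(vhat)
                                                                + self.eps)
            p.data = new.astype(p.data.dtype)
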