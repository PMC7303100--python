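"""Layer modules built on the autodiff core."""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import core
from .core import Tensor
from .functional import same_pads

__all__ = ["Module", "Conv", "Linear", "parameter_count"]


class Module:
    """Base class: recursive parameter discovery over attributes."""

    def parameters(self) -> List[Tensor]:
        out: List[Tensor] = []
        seen: set[int] = set()
        self._collect(out, seen)
        return out

    def _collect(self, out: List[Tensor], seen: set) -> None:
        for value in self.__dict__.values():
            self._collect_value(value, out, seen)

    @staticmethod
    def _collect_value(value, out: List[Tensor], seen: set) -> None:
        if isinstance(value, Tensor):
            if value.requires_grad and id(value) not in seen:
                seen.add(id(value))
                out.append(value)
        elif isinstance(value, Module):
            value._collect(out, seen)
        elif isinstance(value, (list, tuple)):
            for v in value:
                Module._collect_value(v, out, seen)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- weight (de)serialization ------------------------------------------
    def state_arrays(self) -> List[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=p.data.dtype)


def parameter_count(module: Module) -> int:
    """Number of independent trainable scalars (shared storage counted once)."""
    return int(sum(p.data.size for p in module.parameters()))


class Conv(Module):
    """N-dimensional convolution layer (channels-last), He-initialized.

    ``kernel`` has one entry per convolved axis: three entries give a 3D
    volumetric convolution, four the spatio-temporal 4D one.  ``padding`` is
    ``"same"`` (stride-1 size preserving, even kernels pad the trailing edge)
    or ``"valid"``.
    """

    def __init__(self, c_in: int, c_out: int, kernel: Sequence[int],
                 rng: np.random.Generator, padding: str = "same",
                 strides: Optional[Sequence[int]] = None,
                 dtype=np.float32):
        kernel = tuple(int(k) for k in kernel)
        fan_in = c_in * int(np.prod(kernel))
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, size=(*kernel, c_in, c_out)).astype(dtype),
            requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)
        if padding == "same":
            self.pads: Tuple[Tuple[int, int], ...] = same_pads(kernel)
        elif padding == "valid":
            self.pads = tuple((0, 0) for _ in kernel)
        else:
            raise ValueError(f"unknown padding policy {padding!r}")
        self.strides = tuple(strides) if strides is not None else (1,) * len(kernel)

    def __call__(self, x: Tensor) -> Tensor:
        return core.conv(x, self.weight, self.bias, self.pads, self.strides)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        std = np.sqrt(1.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, std, size=(n_in, n_out)).astype(dtype),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return core.linear(x, self.weight, self.bias)
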