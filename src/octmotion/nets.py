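"""The five motion-estimation architectures.

Every model maps a sequence of co-registered OCT volumes to the relative
translation (mm) between the first and the last volume.  All architectures
share the same backbone recipe: an initial processing stage followed by a
densely connected trunk of three dense blocks (2 layers each, growth rate
10) joined by average pooling, global average pooling (GAP) and a linear
3-vector regression head.  They differ only in how temporal information
enters:

``two_path_3d``
    Two weight-shared 3D convolutional paths on the first and last volume,
    fused by channel concatenation, 3D trunk.
``s_two_path_3d``
    The same two-path network applied to the four consecutive pairs of the
    sequence; the pairwise estimates are summed to form the prediction and
    the whole stack is trained end-to-end through that sum.
``five_path_3d``
    Five weight-shared 3D paths, fused by channel concatenation, 3D trunk.
``dense4d``
    Three initial 4D convolutions on the full (5, 32, 32, 32) tensor and a
    4D trunk — spatio-temporal features throughout.
``five_path_4d``
    Five weight-shared 3D paths whose outputs are reassembled into a
    temporal axis, processed by a 4D trunk.

With ``aux_outputs`` enabled a model additionally predicts the shifts at
the two preceding time steps from the same GAP features; these auxiliary
heads exist for training-time temporal regularization only.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import nn
from .nn import Tensor
from .nn.core import (avg_pool, concat, global_mean, instance_norm,
                      leaky_relu, moveaxis, relu, reshape)
from .nn.functional import correlate_nd, same_pads
from .trajectories import SEQUENCE_LENGTH, MotionSequence

__all__ = [
    "MODEL_NAMES",
    "ModelConfig",
    "Prediction",
    "conv4d",
    "DenseBlock",
    "BaselineTrunk",
    "MotionModel",
    "build_model",
    "forward",
    "count_parameters",
]

MODEL_NAMES = ("two_path_3d", "s_two_path_3d", "five_path_3d",
               "dense4d", "five_path_4d")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters left open by the backbone recipe.

    The dense-trunk structure (three blocks of two layers, growth rate 10)
    is the fixed backbone; kernel sizes, path widths, normalization and the
    stem strides are free and externalized here.  ``stem_strides`` gives the
    per-layer isotropic spatial stride of the three initial convolutions;
    (1, 1, 1) keeps full resolution, (2, 2, 1) trades resolution for speed
    on CPU-only training.
    """

    spatial_kernel: int = 3
    temporal_kernel: int = 2
    initial_channels: Tuple[int, int, int] = (8, 16, 32)
    growth_rate: int = 10
    layers_per_block: int = 2
    n_blocks: int = 3
    pool_factor: int = 2
    activation: str = "relu"
    use_norm: bool = False
    aux_outputs: bool = False
    stem_strides: Tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self):
        if self.spatial_kernel % 2 != 1:
            raise ValueError("spatial_kernel must be odd")
        if self.activation not in ("relu", "leaky_relu"):
            raise ValueError("activation must be 'relu' or 'leaky_relu'")
        if len(self.initial_channels) != 3 or len(self.stem_strides) != 3:
            raise ValueError("initial_channels and stem_strides take 3 entries")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["initial_channels"] = list(self.initial_channels)
        d["stem_strides"] = list(self.stem_strides)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for k in ("initial_channels", "stem_strides"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class Prediction:
    """Predicted relative shifts (mm): final step and optional aux steps."""

    y_tn: np.ndarray
    y_tn1: Optional[np.ndarray] = None
    y_tn2: Optional[np.ndarray] = None


def conv4d(input: np.ndarray, kernel: np.ndarray,
           bias: Optional[np.ndarray] = None,
           padding: str = "valid") -> np.ndarray:
    """4D spatio-temporal cross-correlation of a (T, X, Y, Z, C) tensor.

    ``output[t, x, y, z, o] = bias[o] + sum over (tau, i, j, k, c) of
    input[t + tau - off, ...] * kernel[tau, i, j, k, c, o]`` under the given
    padding policy (``valid`` or ``same``).  This is the forward definition;
    the differentiable layer form used inside models is ``nn.Conv`` with a
    four-entry kernel.
    """
    input = np.asarray(input)
    kernel = np.asarray(kernel)
    if kernel.ndim != 6:
        raise ValueError(f"conv4d kernel must be 6-dimensional, got {kernel.ndim}")
    if input.ndim != 5:
        raise ValueError(f"conv4d input must be (T, X, Y, Z, C), got {input.shape}")
    if padding == "same":
        pads = same_pads(kernel.shape[:4])
    elif padding == "valid":
        pads = tuple((0, 0) for _ in range(4))
    else:
        raise ValueError(f"unknown padding policy {padding!r}")
    y = correlate_nd(input[None], kernel, pads)[0]
    if bias is not None:
        y = y + np.asarray(bias)
    return y


def _act(x: Tensor, kind: str) -> Tensor:
    return relu(x) if kind == "relu" else leaky_relu(x)


class _NormAct(nn.Module):
    """Optional instance norm followed by the activation."""

    def __init__(self, channels: int, cfg: ModelConfig):
        self.enabled = cfg.use_norm
        self.kind = cfg.activation
        if self.enabled:
            self.gain = Tensor(np.ones(channels, dtype=np.float32),
                               requires_grad=True)
            self.bias = Tensor(np.zeros(channels, dtype=np.float32),
                               requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        if self.enabled:
            x = instance_norm(x, self.gain, self.bias)
        return _act(x, self.kind)


def _kernel(nd: int, cfg: ModelConfig) -> Tuple[int, ...]:
    if nd == 3:
        return (cfg.spatial_kernel,) * 3
    if nd == 4:
        return (cfg.temporal_kernel,) + (cfg.spatial_kernel,) * 3
    raise ValueError(f"dim must be 3 or 4, got {nd}")


class DenseBlock(nn.Module):
    """Densely connected block: each layer convolves the running
    concatenation and appends ``growth_rate`` feature maps."""

    def __init__(self, c_in: int, nd: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        kernel = _kernel(nd, cfg)
        self.convs: List[nn.Conv] = []
        self.acts: List[_NormAct] = []
        c = c_in
        for _ in range(cfg.layers_per_block):
            self.convs.append(nn.Conv(c, cfg.growth_rate, kernel, rng,
                                      padding="same"))
            self.acts.append(_NormAct(cfg.growth_rate, cfg))
            c += cfg.growth_rate
        self.out_channels = c

    def __call__(self, x: Tensor) -> Tensor:
        feats = x
        for cv, act in zip(self.convs, self.acts):
            new = act(cv(feats))
            feats = concat([feats, new], axis=-1)
        return feats


class BaselineTrunk(nn.Module):
    """Dense blocks joined by average pooling, ending in GAP.

    For ``nd == 4`` the pooling between blocks also pools the temporal axis
    (ceil semantics) while more than one frame remains, so deep 4D blocks
    stay genuinely spatio-temporal.  Output feature length is
    ``c_in + n_blocks * layers_per_block * growth_rate``.
    """

    def __init__(self, c_in: int, nd: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        self.nd = nd
        self.cfg = cfg
        self.blocks: List[DenseBlock] = []
        c = c_in
        for _ in range(cfg.n_blocks):
            block = DenseBlock(c, nd, cfg, rng)
            self.blocks.append(block)
            c = block.out_channels
        self.out_channels = c

    def __call__(self, x: Tensor) -> Tensor:
        nd = self.nd
        spatial_axes = tuple(range(x.ndim - 4, x.ndim - 1))
        n_pools = self.cfg.n_blocks - 1
        f = self.cfg.pool_factor
        for ax in spatial_axes:
            if x.shape[ax] % (f ** n_pools) != 0:
                raise ValueError(
                    f"spatial size {x.shape[ax]} not divisible by "
                    f"pool_factor {f} applied {n_pools} times")
        pool_axes = spatial_axes if nd == 3 else (1,) + spatial_axes
        for i, block in enumerate(self.blocks):
            x = block(x)
            if i < len(self.blocks) - 1:
                x = avg_pool(x, pool_axes, (f,) * len(pool_axes))
        return global_mean(x, tuple(range(1, x.ndim - 1)))


class _Stem(nn.Module):
    """Three convolution layers, 3D (per volume) or 4D (whole sequence)."""

    def __init__(self, nd: int, cfg: ModelConfig, rng: np.random.Generator):
        kernel = _kernel(nd, cfg)
        c1, c2, c3 = cfg.initial_channels
        chans = [1, c1, c2, c3]
        self.convs: List[nn.Conv] = []
        self.acts: List[_NormAct] = []
        for i in range(3):
            s = cfg.stem_strides[i]
            strides = (s,) * 3 if nd == 3 else (1,) + (s,) * 3
            self.convs.append(nn.Conv(chans[i], chans[i + 1], kernel, rng,
                                      padding="same", strides=strides))
            self.acts.append(_NormAct(chans[i + 1], cfg))
        self.out_channels = c3

    def __call__(self, x: Tensor) -> Tensor:
        for cv, act in zip(self.convs, self.acts):
            x = act(cv(x))
        return x

    def apply_paths(self, x: np.ndarray) -> Tensor:
        """Run the weight-shared 3D stem over every volume of a batch of
        sequences in one call: (N, T, X, Y, Z) -> (N, T, X', Y', Z', C)."""
        n, t = x.shape[:2]
        flat = self(Tensor(x.reshape(n * t, *x.shape[2:])[..., None]))
        return reshape(flat, (n, t, *flat.shape[1:]))


class _Heads(nn.Module):
    """Linear regression head(s) from the GAP feature vector."""

    def __init__(self, n_features: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        self.main = nn.Linear(n_features, 3, rng)
        self.aux = cfg.aux_outputs
        if self.aux:
            self.head_tn1 = nn.Linear(n_features, 3, rng)
            self.head_tn2 = nn.Linear(n_features, 3, rng)

    def __call__(self, feats: Tensor) -> Dict[str, Tensor]:
        out = {"y_tn": self.main(feats)}
        if self.aux:
            out["y_tn1"] = self.head_tn1(feats)
            out["y_tn2"] = self.head_tn2(feats)
        return out


def _validate_batch(x: np.ndarray, n_steps: int) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 5:
        raise ValueError(
            f"expected input (N, {n_steps}, X, Y, Z), got shape {x.shape}")
    if x.shape[1] != n_steps:
        raise ValueError(
            f"architecture consumes {n_steps} volumes per sequence, "
            f"got {x.shape[1]}")
    if not (x.shape[2] == x.shape[3]):
        raise ValueError(
            f"lateral axes must match, got spatial shape {x.shape[2:]}; "
            "is the input layout (N, time, x, y, z)?")
    return x


class MotionModel(nn.Module):
    """Base class; concrete architectures implement ``forward_batch``."""

    name: str = ""
    n_inputs: int = SEQUENCE_LENGTH

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg

    def forward_batch(self, x: np.ndarray) -> Dict[str, Tensor]:
        raise NotImplementedError

    def predict_batch(self, x: np.ndarray, batch_size: int = 25) -> np.ndarray:
        """Main-head predictions (N, 3) in mm, batched, no gradient tape."""
        x = np.asarray(x)
        outs = []
        with nn.core.no_grad():
            for i in range(0, x.shape[0], batch_size):
                outs.append(
                    self.forward_batch(x[i:i + batch_size])["y_tn"].data)
        return np.concatenate(outs, axis=0)


class TwoPath3D(MotionModel):
    """Weight-shared two-path 3D CNN on the first and last volume."""

    name = "two_path_3d"

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__(cfg)
        self.stem = _Stem(3, cfg, rng)
        self.trunk = BaselineTrunk(2 * self.stem.out_channels, 3, cfg, rng)
        self.heads = _Heads(self.trunk.out_channels, cfg, rng)

    def forward_batch(self, x: np.ndarray) -> Dict[str, Tensor]:
        x = np.asarray(x)
        if x.ndim == 5 and x.shape[1] == SEQUENCE_LENGTH:
            x = x[:, [0, -1]]
        x = _validate_batch(x, 2)
        f = self.stem.apply_paths(x)           # (N, 2, X', Y', Z', C)
        f = reshape(moveaxis(f, 1, -2), (*f.shape[0:1], *f.shape[2:5],
                                         2 * f.shape[-1]))
        return self.heads(self.trunk(f))


class STwoPath3D(MotionModel):
    """Two-path network applied to consecutive pairs, estimates summed.

    The pairwise network is a full :class:`TwoPath3D` (identical topology and
    shared storage, hence identical parameter count); training is end-to-end
    through the summed prediction.
    """

    name = "s_two_path_3d"

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__(cfg)
        self.pair_net = TwoPath3D(cfg, rng)

    def forward_batch(self, x: np.ndarray) -> Dict[str, Tensor]:
        x = _validate_batch(np.asarray(x), SEQUENCE_LENGTH)
        partial: Dict[str, Tensor] = {}
        for t in range(SEQUENCE_LENGTH - 1):
            out = self.pair_net.forward_batch(x[:, [t, t + 1]])
            for k, v in out.items():
                partial[k] = v if k not in partial else nn.core.add(partial[k], v)
        return partial


class FivePath3D(MotionModel):
    """Five weight-shared 3D paths fused by channel concatenation."""

    name = "five_path_3d"

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__(cfg)
        self.stem = _Stem(3, cfg, rng)
        self.trunk = BaselineTrunk(SEQUENCE_LENGTH * self.stem.out_channels,
                                   3, cfg, rng)
        self.heads = _Heads(self.trunk.out_channels, cfg, rng)

    def forward_batch(self, x: np.ndarray) -> Dict[str, Tensor]:
        x = _validate_batch(np.asarray(x), SEQUENCE_LENGTH)
        f = self.stem.apply_paths(x)
        f = reshape(moveaxis(f, 1, -2), (*f.shape[0:1], *f.shape[2:5],
                                         SEQUENCE_LENGTH * f.shape[-1]))
        return self.heads(self.trunk(f))


class Dense4D(MotionModel):
    """Fully 4D network: spatio-temporal convolutions from the first layer."""

    name = "dense4d"

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__(cfg)
        self.stem = _Stem(4, cfg, rng)
        self.trunk = BaselineTrunk(self.stem.out_channels, 4, cfg, rng)
        self.heads = _Heads(self.trunk.out_channels, cfg, rng)

    def forward_batch(self, x: np.ndarray) -> Dict[str, Tensor]:
        x = _validate_batch(np.asarray(x), SEQUENCE_LENGTH)
        feats = self.stem(Tensor(x[..., None]))
        return self.heads(self.trunk(feats))


class FivePath4D(MotionModel):
    """Five shared 3D paths reassembled into a temporal axis, 4D trunk."""

    name = "five_path_4d"

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__(cfg)
        self.stem = _Stem(3, cfg, rng)
        self.trunk = BaselineTrunk(self.stem.out_channels, 4, cfg, rng)
        self.heads = _Heads(self.trunk.out_channels, cfg, rng)

    def forward_batch(self, x: np.ndarray) -> Dict[str, Tensor]:
        x = _validate_batch(np.asarray(x), SEQUENCE_LENGTH)
        feats = self.stem.apply_paths(x)       # time axis restored at 1
        return self.heads(self.trunk(feats))


_BUILDERS = {
    "two_path_3d": TwoPath3D,
    "s_two_path_3d": STwoPath3D,
    "five_path_3d": FivePath3D,
    "dense4d": Dense4D,
    "five_path_4d": FivePath4D,
}


def build_model(name: str, config: ModelConfig | None = None,
                seed: int = 0) -> MotionModel:
    """Instantiate one of the five architectures with seeded init."""
    if name not in _BUILDERS:
        raise ValueError(f"unknown architecture {name!r}; "
                         f"choose from {MODEL_NAMES}")
    cfg = config if config is not None else ModelConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x4D]))
    return _BUILDERS[name](cfg, rng)


def forward(model: MotionModel, seq: MotionSequence) -> Prediction:
    """Run one motion sequence through a model."""
    out = model.forward_batch(np.asarray(seq.volumes)[None].astype(np.float32))
    return Prediction(
        y_tn=out["y_tn"].data[0],
        y_tn1=out["y_tn1"].data[0] if "y_tn1" in out else None,
        y_tn2=out["y_tn2"].data[0] if "y_tn2" in out else None,
    )


def count_parameters(model: nn.Module) -> int:
    """Independent trainable scalars; shared path weights counted once."""
    return nn.parameter_count(model)
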