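"""Loss functions, ROI-wise splits and the training loop.

The primary objective is the batch-mean squared Euclidean error between the
target shift of the final step and the prediction.  The temporally
regularized variant adds the squared errors of the two preceding steps,
weighted by ``w_n1`` and ``w_n2`` in [0, 1]; with both weights zero it is
bit-identical to the plain objective.  Targets are kept in mm.

Splits are made at the level of tissue regions (ROIs), never sequences, so
no tissue region ever appears in more than one of train/val/test.
"""

from __future__ import annotations

import time
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .nn import Adam, Tensor
from .nn.core import add, mean_squared_norm, scale
from .nets import MotionModel
from .trajectories import MotionSequence, sequences_to_arrays

__all__ = [
    "LossConfig",
    "TrainConfig",
    "RoiSplit",
    "TrainingDiverged",
    "loss",
    "split_rois",
    "train",
    "TrainResult",
]


class TrainingDiverged(RuntimeError):
    """The training loss became non-finite."""


@dataclass(frozen=True)
class LossConfig:
    """Weights of the auxiliary temporal targets (both in [0, 1])."""

    w_n1: float = 0.0
    w_n2: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.w_n1 <= 1.0 and 0.0 <= self.w_n2 <= 1.0):
            raise ValueError("loss weights must lie in [0, 1]")

    @property
    def needs_aux(self) -> bool:
        return self.w_n1 > 0.0 or self.w_n2 > 0.0


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol; defaults follow the full-scale recipe
    (Adam, batch 50, 150 epochs)."""

    epochs: int = 150
    batch_size: int = 50
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    seed: int = 0
    clip_norm: float = 5.0  # global gradient-norm clip; 0 disables
    lr_schedule: str = "constant"  # or "cosine" (anneals to lr/10)
    average_tail: int = 0  # >0: final weights = mean of the last k epochs

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the Adam optimizer is provided")


def loss(preds: Dict[str, Tensor], targets: Tuple[np.ndarray, ...],
         cfg: LossConfig) -> Tensor:
    """Batch-mean squared-norm loss with optional temporal regularization.

    ``preds`` maps head names (``y_tn`` and optionally ``y_tn1``/``y_tn2``)
    to (N, 3) prediction tensors; ``targets`` is the matching triple
    ``(shift_tn, shift_tn1, shift_tn2)`` of (N, 3) arrays (the auxiliary
    entries may be None when the corresponding weights are zero).
    """
    t_n, t_n1, t_n2 = targets
    t_n = np.asarray(t_n)
    if t_n.ndim != 2 or t_n.shape[0] == 0:
        raise ValueError("empty batch")
    total = mean_squared_norm(preds["y_tn"], t_n)
    for w, key, tgt in ((cfg.w_n1, "y_tn1", t_n1), (cfg.w_n2, "y_tn2", t_n2)):
        if w == 0.0:
            continue
        if key not in preds:
            raise ValueError(
                f"loss weight for {key} is {w} but the model does not "
                "predict it; build it with aux_outputs enabled")
        if tgt is None:
            raise ValueError(f"auxiliary target for {key} missing")
        total = add(total, scale(mean_squared_norm(preds[key], np.asarray(tgt)), w))
    return total


class RoiSplit(NamedTuple):
    train: Tuple[int, ...]
    val: Tuple[int, ...]
    test: Tuple[int, ...]


def split_rois(roi_ids: Sequence[int], n_test: int = 5, n_val: int = 5,
               seed: int = 0) -> RoiSplit:
    """Random disjoint ROI-wise train/val/test split covering all ids."""
    ids = np.unique(np.asarray(roi_ids, dtype=int))
    if len(ids) <= n_test + n_val:
        raise ValueError(
            f"{len(ids)} ROIs cannot supply {n_test} test + {n_val} val "
            "ROIs and still leave a training set")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5F11]))
    perm = rng.permutation(ids)
    test = tuple(sorted(int(i) for i in perm[:n_test]))
    val = tuple(sorted(int(i) for i in perm[n_test:n_test + n_val]))
    train = tuple(sorted(int(i) for i in perm[n_test + n_val:]))
    return RoiSplit(train=train, val=val, test=test)


def _targets_for(shifts: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(final, previous, pre-previous) step targets from (N, 5, 3) shifts."""
    return shifts[:, -1], shifts[:, -2], shifts[:, -3]


@dataclass
class TrainResult:
    model: MotionModel
    history: pd.DataFrame
    best_epoch: int
    best_val_loss: float
    final_state: List[np.ndarray] = field(repr=False, default_factory=list)


def _eval_loss(model: MotionModel, x: np.ndarray, y: np.ndarray,
               lcfg: LossConfig, batch_size: int) -> float:
    from .nn.core import no_grad

    tot, n = 0.0, 0
    with no_grad():
        for i in range(0, x.shape[0], batch_size):
            xb, yb = x[i:i + batch_size], y[i:i + batch_size]
            preds = model.forward_batch(xb)
            tot += loss(preds, _targets_for(yb), lcfg).item() * xb.shape[0]
            n += xb.shape[0]
    return tot / max(n, 1)


def train(model: MotionModel,
          dataset: Sequence[MotionSequence] | Tuple[np.ndarray, np.ndarray],
          tcfg: TrainConfig, lcfg: LossConfig | None = None,
          val_dataset: Optional[Sequence[MotionSequence]
                                | Tuple[np.ndarray, np.ndarray]] = None,
          log_fn=None) -> TrainResult:
    """Minimize the (regularized) loss with Adam over shuffled mini-batches.

    Records per-epoch train/val losses.  On return the model carries the
    tail-averaged weights when ``tcfg.average_tail > 0``, otherwise the
    best-validation checkpoint (or the final weights without a validation
    set); the final epoch's parameters are always kept in
    ``TrainResult.final_state``.  Fully deterministic for a fixed
    ``tcfg.seed``.
    """
    lcfg = lcfg if lcfg is not None else LossConfig()
    if lcfg.needs_aux and not model.cfg.aux_outputs:
        raise ValueError("regularized loss requires a model built with "
                         "aux_outputs=True")

    if isinstance(dataset, tuple):
        x, y = dataset
    else:
        x, y, _ = sequences_to_arrays(dataset)
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)

    xv = yv = None
    if val_dataset is not None:
        if isinstance(val_dataset, tuple):
            xv, yv = val_dataset
        else:
            xv, yv, _ = sequences_to_arrays(val_dataset)
        xv = np.asarray(xv, dtype=np.float32)
        yv = np.asarray(yv, dtype=np.float32)

    rng = np.random.default_rng(np.random.SeedSequence([int(tcfg.seed), 0x7124]))
    opt = Adam(model.parameters(), lr=tcfg.learning_rate)
    # the clip bounds the gradient of the unit-weight objective; the
    # regularized loss is (1 + w_n1 + w_n2) times larger in scale, so the
    # bound scales with it to keep the effective step size comparable
    clip_limit = tcfg.clip_norm * (1.0 + lcfg.w_n1 + lcfg.w_n2)
    best_val = np.inf
    best_state = [p.data.copy() for p in model.parameters()]
    best_epoch = 0
    rows = []
    tail: deque = deque(maxlen=max(tcfg.average_tail, 1))
    n = x.shape[0]
    for epoch in range(tcfg.epochs):
        t0 = time.perf_counter()
        if tcfg.lr_schedule == "cosine":
            frac = epoch / max(1, tcfg.epochs - 1)
            # plain python float: a numpy scalar would promote the float32
            # parameters to float64 through the update expression
            opt.lr = float(tcfg.learning_rate
                           * (0.55 + 0.45 * np.cos(np.pi * frac)))
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for i in range(0, n, tcfg.batch_size):
            idx = order[i:i + tcfg.batch_size]
            preds = model.forward_batch(x[idx])
            batch_loss = loss(preds, _targets_for(y[idx]), lcfg)
            value = batch_loss.item()
            if not np.isfinite(value):
                raise TrainingDiverged(
                    f"non-finite training loss at epoch {epoch}, batch "
                    f"{i // tcfg.batch_size}: {value}")
            opt.zero_grad()
            batch_loss.backward()
            if tcfg.clip_norm > 0:
                total = float(np.sqrt(sum(
                    float((p.grad ** 2).sum())
                    for p in opt.params if p.grad is not None)))
                if total > clip_limit:
                    factor = float(clip_limit / total)  # keep float32 grads
                    for p in opt.params:
                        if p.grad is not None:
                            p.grad = p.grad * factor
            opt.step()
            epoch_loss += value * len(idx)
            seen += len(idx)
        train_loss = epoch_loss / seen
        if tcfg.average_tail > 0:
            tail.append([p.data.copy() for p in model.parameters()])
        val_loss = (_eval_loss(model, xv, yv, lcfg, tcfg.batch_size)
                    if xv is not None else np.nan)
        if xv is not None and val_loss < best_val:
            best_val = val_loss
            best_state = [p.data.copy() for p in model.parameters()]
            best_epoch = epoch
        rows.append({"epoch": epoch, "train_loss": train_loss,
                     "val_loss": val_loss,
                     "wall_time_s": time.perf_counter() - t0})
        if log_fn is not None:
            log_fn(rows[-1])

    final_state = [p.data.copy() for p in model.parameters()]
    if xv is None:
        best_val = rows[-1]["train_loss"] if rows else np.nan
        best_epoch = len(rows) - 1
    if tcfg.average_tail > 0:
        # stochastic weight averaging over the annealed tail of training
        averaged = [
            np.mean([state[i] for state in tail], axis=0).astype(
                final_state[i].dtype)
            for i in range(len(final_state))]
        model.load_state_arrays(averaged)
    elif xv is not None:
        model.load_state_arrays(best_state)
    return TrainResult(model=model, history=pd.DataFrame(rows),
                       best_epoch=best_epoch, best_val_loss=float(best_val),
                       final_state=final_state)


def save_checkpoint(model: MotionModel, path) -> None:
    """Weights to ``.npz`` plus a YAML sidecar with the architecture config."""
    import yaml
    from pathlib import Path

    path = Path(path)
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, **arrays)
    sidecar = path.with_suffix(".yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump({"arch": model.name, "config": model.cfg.to_dict()}, fh)


def load_checkpoint(path) -> MotionModel:
    import yaml
    from pathlib import Path

    from .nets import ModelConfig, build_model

    path = Path(path)
    with open(path.with_suffix(".yaml")) as fh:
        meta = yaml.safe_load(fh)
    model = build_model(meta["arch"], ModelConfig.from_dict(meta["config"]))
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
        arrays = [data[f"p{i}"] for i in range(len(data.files))]
    model.load_state_arrays(arrays)
    return model
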