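"""The desk-scale benchmark: fixed study conditions on a single CPU core.

This module pins the exact conditions under which the package's headline
properties are measured (and re-measured by the acceptance script and the
trained-model tests): dataset size, architecture widths, optimization
protocol.  Everything derives from one integer seed, so two runs with the
same seed reproduce each other bit for bit.

The conditions are deliberately smaller than the full-scale protocol (40
ROIs × 200 patterns, 150 epochs, full-width models): they are sized so one
architecture trains in minutes on one core while preserving the structure
of the experiment — ROI-wise splits, uniform motion magnitudes up to about
half the FOV, and the five-architecture family.  See docs/methods.md for
the sizing rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .augmentations import DistortionSpec, distort_sequence
from .evaluation import EvalReport, evaluate_model, rmae_samples
from .nets import ModelConfig, MotionModel, build_model
from .trajectories import MotionSequence, build_dataset, sequences_to_arrays
from .training import LossConfig, TrainConfig, TrainResult, split_rois, train

__all__ = [
    "DESK_N_ROIS", "DESK_N_PATTERNS", "DESK_MODEL_CONFIG", "DESK_EPOCHS",
    "DeskData", "desk_data", "desk_model_config", "desk_train_config",
    "train_desk_model", "evaluate_on",
]

# dataset: many tissue regions with few patterns each — held-out-ROI
# generalization is limited by ROI diversity, not pattern count
DESK_N_ROIS = 20
DESK_N_PATTERNS = 50
DESK_N_TEST = 2
DESK_N_VAL = 2

# reduced-width models on decimated feature grids; the wide final stem
# channel is what gives the temporal trunk rich enough per-frame
# descriptors, and the 3-tap temporal kernel lets it form centred
# temporal differences
DESK_MODEL_CONFIG = ModelConfig(
    initial_channels=(8, 16, 24),
    stem_strides=(2, 2, 2),
    activation="leaky_relu",
    temporal_kernel=3,
)

#: per-architecture epoch counts: the spatio-temporal trunks converge later
DESK_EPOCHS = {"two_path_3d": 12, "s_two_path_3d": 12, "five_path_3d": 12,
               "dense4d": 18, "five_path_4d": 18}
#: small batches double the update count per epoch, which is what the
#: late-converging 4D trunks need on an 800-sequence training set
DESK_BATCH = 5
DESK_LR = 3e-3
DESK_AVERAGE_TAIL = 4


@dataclass
class DeskData:
    train: List[MotionSequence]
    val: List[MotionSequence]
    test: List[MotionSequence]

    @property
    def arrays(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        return {k: sequences_to_arrays(getattr(self, k))[:2]
                for k in ("train", "val", "test")}


def desk_data(seed: int) -> DeskData:
    """Simulate the desk dataset and split it ROI-wise."""
    seqs = build_dataset(DESK_N_ROIS, DESK_N_PATTERNS, seed)
    split = split_rois([s.roi_id for s in seqs], n_test=DESK_N_TEST,
                       n_val=DESK_N_VAL, seed=seed)
    return DeskData(
        train=[s for s in seqs if s.roi_id in split.train],
        val=[s for s in seqs if s.roi_id in split.val],
        test=[s for s in seqs if s.roi_id in split.test],
    )


def desk_model_config(aux_outputs: bool = False) -> ModelConfig:
    return replace(DESK_MODEL_CONFIG, aux_outputs=aux_outputs)


def desk_train_config(seed: int, epochs: int) -> TrainConfig:
    return TrainConfig(epochs=epochs, batch_size=DESK_BATCH,
                       learning_rate=DESK_LR, seed=seed, clip_norm=5.0,
                       lr_schedule="cosine", average_tail=DESK_AVERAGE_TAIL)


def train_desk_model(arch: str, data: DeskData, seed: int,
                     loss_cfg: Optional[LossConfig] = None,
                     train_distortion: Optional[DistortionSpec] = None,
                     epochs: Optional[int] = None) -> Tuple[MotionModel, TrainResult]:
    """Train one architecture under the desk conditions.

    ``train_distortion`` applies matched B-scan distortion to the training
    sequences (one fixed draw per run), the augmentation used to study
    recovery from evaluation-time distortion.
    """
    lcfg = loss_cfg if loss_cfg is not None else LossConfig()
    if epochs is None:
        epochs = DESK_EPOCHS.get(arch, 14)
    model = build_model(arch, desk_model_config(aux_outputs=lcfg.needs_aux),
                        seed=seed)
    train_seqs = data.train
    if train_distortion is not None:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), 0xD15]))
        train_seqs = [distort_sequence(s, train_distortion, rng)
                      for s in train_seqs]
    result = train(model, train_seqs, desk_train_config(seed, epochs), lcfg,
                   val_dataset=data.val)
    return model, result


def evaluate_on(model: MotionModel, sequences: Sequence[MotionSequence]
                ) -> Tuple[EvalReport, np.ndarray]:
    """Evaluate and also return per-sample rMAE values for paired tests."""
    x, y, _ = sequences_to_arrays(sequences)
    preds = model.predict_batch(x)
    report = evaluate_model(model, sequences)
    return report, rmae_samples(preds, y[:, -1])
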