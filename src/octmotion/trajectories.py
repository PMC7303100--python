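"""Smooth drift trajectories in shift space and labelled motion sequences.

A motion pattern is a sequence of five FOV shifts starting at the origin:
the tissue region of interest (ROI) stays put while the FOV drifts away
along a smooth curve, so the relative shift of the ROI w.r.t. its initial
position is known exactly at every step.  Each trajectory is built from a
random endpoint and a random connection point via a per-coordinate natural
cubic spline, which produces curved drifts of varying magnitude.

All shifts are *relative to the initial position* (not incremental), and the
first shift is always exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .phantom import (Calibration, Phantom, TextureParams, acquire_volume,
                      make_phantom)

__all__ = [
    "SEQUENCE_LENGTH",
    "DEFAULT_MAGNITUDE_RANGE_MM",
    "AXIAL_SCALE",
    "TrajectorySpec",
    "MotionSequence",
    "sample_trajectory",
    "make_sequence",
    "build_dataset",
    "dataset_manifest",
    "save_dataset",
    "load_dataset",
    "sequences_to_arrays",
]

#: number of target translations (and volumes) per motion pattern
SEQUENCE_LENGTH = 5
#: default endpoint magnitude range, mm (up to about half the lateral FOV)
DEFAULT_MAGNITUDE_RANGE_MM = (0.2, 2.4)
#: compression of the axial direction component (3.5 mm axial vs 5 mm lateral FOV)
AXIAL_SCALE = 3.5 / 5.0

#: spline knot parameters and the parameters at which the five shifts sit
_KNOTS_U = np.array([0.0, 0.5, 1.0])
_SAMPLES_U = np.array([0.0, 0.25, 0.5, 0.75, 1.0])


@dataclass(frozen=True)
class TrajectorySpec:
    """Five target shifts (mm), the spline connection point and |endpoint|."""

    shifts: np.ndarray          # (5, 3) mm, shifts[0] == 0
    connection: np.ndarray      # (3,) mm
    magnitude: float            # |shifts[4]| mm

    def __post_init__(self):
        shifts = np.asarray(self.shifts, dtype=float)
        if shifts.shape != (SEQUENCE_LENGTH, 3):
            raise ValueError(f"expected {SEQUENCE_LENGTH} shifts, got {shifts.shape}")
        if np.any(shifts[0] != 0.0):
            raise ValueError("the first shift must be exactly (0, 0, 0)")
        object.__setattr__(self, "shifts", shifts)
        object.__setattr__(self, "connection",
                           np.asarray(self.connection, dtype=float))


@dataclass
class MotionSequence:
    """Five volumes with their ground-truth relative shifts and ROI id."""

    volumes: np.ndarray         # (5, 32, 32, 32) float32
    shifts: np.ndarray          # (5, 3) mm, relative to the initial position
    roi_id: int

    def __post_init__(self):
        if len(self.volumes) != SEQUENCE_LENGTH or len(self.shifts) != SEQUENCE_LENGTH:
            raise ValueError("a motion sequence holds exactly five volumes "
                             "and five shifts")


def _spline_through(connection: np.ndarray, endpoint: np.ndarray) -> np.ndarray:
    """Five shifts from the natural cubic spline through 0, Δs_c, Δs_4."""
    knots = np.stack([np.zeros(3), connection, endpoint])
    spline = CubicSpline(_KNOTS_U, knots, axis=0, bc_type="natural")
    shifts = spline(_SAMPLES_U)
    shifts[0] = 0.0  # exact by construction; pin against rounding
    shifts[2] = connection
    shifts[4] = endpoint
    return shifts


def sample_trajectory(rng: np.random.Generator,
                      magnitude_range: Tuple[float, float] = DEFAULT_MAGNITUDE_RANGE_MM,
                      connection_sigma_frac: float = 0.15) -> TrajectorySpec:
    """Draw one random five-step drift trajectory.

    The endpoint direction is isotropic with its axial component compressed
    by 3.5/5 (and renormalized) to respect the shallower axial FOV; the
    endpoint magnitude is uniform in ``magnitude_range``.  The connection
    point sits near the midpoint with an isotropic Gaussian perturbation of
    ``connection_sigma_frac * |Δs_4|``, truncated at 2 sigma so trajectories
    stay within the simulatable bounds.
    """
    lo, hi = magnitude_range
    if not (0 < lo <= hi):
        raise ValueError(f"invalid magnitude range {magnitude_range}")

    direction = rng.standard_normal(3)
    norm = np.linalg.norm(direction)
    while norm < 1e-12:  # pragma: no cover - probability ~0
        direction = rng.standard_normal(3)
        norm = np.linalg.norm(direction)
    direction /= norm
    direction[2] *= AXIAL_SCALE
    direction /= np.linalg.norm(direction)

    magnitude = rng.uniform(lo, hi)
    endpoint = magnitude * direction

    sigma = connection_sigma_frac * magnitude
    perturbation = sigma * rng.standard_normal(3)
    pnorm = np.linalg.norm(perturbation)
    if sigma > 0 and pnorm > 2.0 * sigma:
        perturbation *= 2.0 * sigma / pnorm
    connection = endpoint / 2.0 + perturbation

    shifts = _spline_through(connection, endpoint)
    return TrajectorySpec(shifts=shifts, connection=connection,
                          magnitude=float(magnitude))


def make_sequence(phantom: Phantom, traj: TrajectorySpec,
                  calibration: Calibration | None = None,
                  roi_id: int = 0) -> MotionSequence:
    """Acquire the five volumes of a trajectory from a phantom."""
    cal = calibration if calibration is not None else Calibration()
    volumes = np.stack([acquire_volume(phantom, s, cal) for s in traj.shifts])
    return MotionSequence(volumes=volumes, shifts=traj.shifts.copy(),
                          roi_id=int(roi_id))


def build_dataset(n_rois: int, n_patterns: int, seed: int,
                  magnitude_range: Tuple[float, float] = DEFAULT_MAGNITUDE_RANGE_MM,
                  grid_size: Sequence[int] = (96, 96, 96),
                  texture_params: TextureParams | None = None,
                  calibration: Calibration | None = None) -> List[MotionSequence]:
    """Simulate ``n_rois x n_patterns`` labelled motion sequences.

    Each ROI is an independently seeded phantom (a distinct tissue region);
    every sequence is tagged with its ROI id so splits can be made ROI-wise.
    The desk-scale profile is 8 ROIs x 25 patterns; the full-scale profile of
    40 x 200 uses the same code path.
    """
    if n_rois < 3:
        raise ValueError("need at least 3 ROIs to allow a train/val/test split")
    cal = calibration if calibration is not None else Calibration()
    root = np.random.SeedSequence(int(seed))
    roi_seeds = root.spawn(n_rois)
    sequences: List[MotionSequence] = []
    for roi_id, roi_ss in enumerate(roi_seeds):
        phantom_seed = int(roi_ss.generate_state(1)[0] % (2 ** 31))
        phantom = make_phantom(phantom_seed, grid_size, texture_params)
        rng = np.random.default_rng(roi_ss.spawn(1)[0])
        for _ in range(n_patterns):
            traj = sample_trajectory(rng, magnitude_range)
            sequences.append(make_sequence(phantom, traj, cal, roi_id))
    return sequences


def dataset_manifest(sequences: Sequence[MotionSequence]) -> pd.DataFrame:
    """One row per sequence: roi_id and the five shifts in mm."""
    rows = []
    for i, seq in enumerate(sequences):
        row = {"sequence": i, "roi_id": seq.roi_id}
        for t in range(SEQUENCE_LENGTH):
            for ax, name in enumerate("xyz"):
                row[f"shift{t}_{name}_mm"] = seq.shifts[t, ax]
        rows.append(row)
    return pd.DataFrame(rows)


def sequences_to_arrays(sequences: Sequence[MotionSequence]
                        ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack a dataset into (volumes, shifts, roi_ids) arrays.

    volumes: (N, 5, 32, 32, 32) float32; shifts: (N, 5, 3) float64 mm.
    """
    x = np.stack([s.volumes for s in sequences]).astype(np.float32)
    y = np.stack([s.shifts for s in sequences])
    rois = np.array([s.roi_id for s in sequences], dtype=int)
    return x, y, rois


def save_dataset(sequences: Sequence[MotionSequence], path: str | Path,
                 seed: int | None = None) -> None:
    """Persist a dataset to a chunked zarr store plus a CSV manifest."""
    import zarr

    path = Path(path)
    x, y, rois = sequences_to_arrays(sequences)
    store = zarr.open_group(str(path / "sequences.zarr"), mode="w")
    arr = store.create_array("volumes", shape=x.shape, dtype="float32",
                             chunks=(1, *x.shape[1:]))
    arr[:] = x
    store.create_array("shifts_mm", shape=y.shape, dtype="float64")[:] = y
    store.create_array("roi_ids", shape=rois.shape, dtype="int64")[:] = rois
    store.attrs["n_sequences"] = int(len(sequences))
    if seed is not None:
        store.attrs["seed"] = int(seed)
    dataset_manifest(sequences).to_csv(path / "manifest.csv", index=False)


def load_dataset(path: str | Path) -> List[MotionSequence]:
    import zarr

    store = zarr.open_group(str(Path(path) / "sequences.zarr"), mode="r")
    x = np.asarray(store["volumes"])
    y = np.asarray(store["shifts_mm"])
    rois = np.asarray(store["roi_ids"])
    return [MotionSequence(volumes=x[i], shifts=y[i], roi_id=int(rois[i]))
            for i in range(x.shape[0])]


def export_volume_tiff(volume: np.ndarray, path: str | Path) -> None:
    """Write one volume as a 32-page TIFF (pages along depth) for inspection."""
    import tifffile

    vol = np.asarray(volume, dtype=np.float32)
    tifffile.imwrite(str(path), np.moveaxis(vol, 2, 0))
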