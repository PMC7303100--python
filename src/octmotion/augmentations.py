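"""Post-acquisition augmentations: axial-axis rotations and B-scan distortion.

Rotations emulate relative rotation building up over a sequence: volume ``i``
is rotated about the depth (z) axis by ``alpha_i = alpha_max / 4 * i``.  In
``noise`` mode the labels are untouched (rotation is an unmodelled nuisance);
in ``motion`` mode the rotation is treated as part of the motion and the
lateral label components of step ``i`` are mapped with the in-plane rotation
matrix ``R(alpha_i)`` (the axial component is unchanged).

B-scan motion distortion emulates fast irregular motion during a raster
scan: each B-scan (a plane at fixed slow-axis index y) is independently
shifted by one or two voxels along one in-plane axis with probability
``p_dist``.

Sign convention: positive angles rotate counterclockwise about +z when
viewed from +z.  Resampling is bilinear about the volume centre with
out-of-support voxels filled by edge replication, so no dark border
correlated with the label is introduced.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.ndimage import map_coordinates

from .trajectories import SEQUENCE_LENGTH, MotionSequence

__all__ = [
    "RotationSpec",
    "DistortionSpec",
    "rotation_angles",
    "rotate_volume_z",
    "rotate_sequence",
    "distort_volume",
    "distort_sequence",
]


@dataclass(frozen=True)
class RotationSpec:
    """Maximal rotation (deg) reached by the last volume, and label mode."""

    alpha_max: float
    mode: str = "noise"

    def __post_init__(self):
        if self.alpha_max < 0:
            raise ValueError("alpha_max must be non-negative")
        if self.mode not in ("noise", "motion"):
            raise ValueError(f"mode must be 'noise' or 'motion', got {self.mode!r}")


@dataclass(frozen=True)
class DistortionSpec:
    """Per-B-scan shift probability and shift size in voxels (1 or 2)."""

    p_dist: float
    shift_px: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_dist <= 1.0:
            raise ValueError("p_dist must lie in [0, 1]")
        if self.shift_px not in (1, 2):
            raise ValueError("shift_px must be 1 or 2")


def rotation_angles(alpha_max: float) -> np.ndarray:
    """Per-volume angles ``alpha_max / 4 * i`` for i in 0..4, degrees."""
    return alpha_max / 4.0 * np.arange(SEQUENCE_LENGTH, dtype=float)


def _rot2d(alpha_deg: float) -> np.ndarray:
    a = np.deg2rad(alpha_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


def rotate_volume_z(volume: np.ndarray, alpha_deg: float) -> np.ndarray:
    """Rotate a volume counterclockwise about +z by ``alpha_deg`` degrees.

    Bilinear in-plane resampling about the lateral centre (index 15.5);
    voxels rotated in from outside the support replicate the nearest edge.
    """
    if alpha_deg == 0.0:
        return volume.copy()
    vol = np.asarray(volume)
    nx, ny, nz = vol.shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    # inverse map: source = c + R(-alpha) (target - c)
    rinv = _rot2d(-alpha_deg)
    sx = cx + rinv[0, 0] * (xs - cx) + rinv[0, 1] * (ys - cy)
    sy = cy + rinv[1, 0] * (xs - cx) + rinv[1, 1] * (ys - cy)
    out = np.empty_like(vol, dtype=np.float32)
    coords = np.stack([sx.ravel(), sy.ravel()])
    for z in range(nz):
        out[:, :, z] = map_coordinates(
            vol[:, :, z], coords, order=1, mode="nearest").reshape(nx, ny)
    return out


def rotate_sequence(seq: MotionSequence, spec: RotationSpec) -> MotionSequence:
    """Apply the ramped rotation ``R(alpha_i) x_i`` to a motion sequence."""
    if len(seq.volumes) != SEQUENCE_LENGTH:
        raise ValueError("rotation expects a five-volume sequence")
    if spec.alpha_max == 0.0:
        return MotionSequence(volumes=seq.volumes.copy(),
                              shifts=seq.shifts.copy(), roi_id=seq.roi_id)
    angles = rotation_angles(spec.alpha_max)
    volumes = np.stack([rotate_volume_z(v, a)
                        for v, a in zip(seq.volumes, angles)])
    shifts = seq.shifts.copy()
    if spec.mode == "motion":
        for i, a in enumerate(angles):
            shifts[i, :2] = _rot2d(a) @ shifts[i, :2]
    return MotionSequence(volumes=volumes, shifts=shifts, roi_id=seq.roi_id)


def _shift_bscan(plane: np.ndarray, axis: int, amount: int) -> np.ndarray:
    """Shift a 2D (x, z) B-scan by ``amount`` voxels with edge replication."""
    out = np.empty_like(plane)
    s = amount
    if axis == 0:
        if s > 0:
            out[s:, :] = plane[:-s, :]
            out[:s, :] = plane[0:1, :]
        else:
            out[:s, :] = plane[-s:, :]
            out[s:, :] = plane[-1:, :]
    else:
        if s > 0:
            out[:, s:] = plane[:, :-s]
            out[:, :s] = plane[:, 0:1]
        else:
            out[:, :s] = plane[:, -s:]
            out[:, s:] = plane[:, -1:]
    return out


def distort_volume(vol: np.ndarray, spec: DistortionSpec,
                   rng: np.random.Generator,
                   return_info: bool = False):
    """Randomly displace individual B-scans of a volume.

    Each of the 32 B-scans (fixed y index) is independently selected with
    probability ``p_dist``; a selected B-scan is translated by ``shift_px``
    voxels along one uniformly chosen in-plane axis (x or z) with uniformly
    chosen sign, vacated voxels filled by edge replication.  With
    ``return_info=True`` also returns the per-B-scan displacement record
    (n_y, 2) of (axis, signed amount), axis -1 meaning untouched.
    """
    vol = np.asarray(vol)
    ny = vol.shape[1]
    selected = rng.random(ny) < spec.p_dist
    axes = rng.integers(0, 2, size=ny)
    signs = np.where(rng.integers(0, 2, size=ny) == 0, -1, 1)
    out = vol.copy()
    info = np.full((ny, 2), -1, dtype=int)
    for y in np.nonzero(selected)[0]:
        amount = int(signs[y]) * spec.shift_px
        out[:, y, :] = _shift_bscan(vol[:, y, :], int(axes[y]), amount)
        info[y] = (axes[y], amount)
    if return_info:
        return out, info
    return out


def distort_sequence(seq: MotionSequence, spec: DistortionSpec,
                     rng: np.random.Generator) -> MotionSequence:
    """Distort every volume of a sequence independently; labels unchanged."""
    volumes = np.stack([distort_volume(v, spec, rng) for v in seq.volumes])
    return MotionSequence(volumes=volumes, shifts=seq.shifts.copy(),
                          roi_id=seq.roi_id)
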