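"""Synthetic speckle tissue phantoms and sub-voxel volume acquisition.

This module stands in for the physical acquisition rig: a swept-source OCT
scan head whose field of view (FOV) is steered by galvo mirrors (lateral) and
by the reference-arm pathlength (axial).  A :class:`Phantom` is a large
master grid of scatter amplitudes representing a fixed tissue region;
:func:`acquire_volume` crops a 32x32x32 FOV out of it at an arbitrary
sub-voxel shift, which is exactly the "move the FOV, keep the tissue still"
trick used to generate ground-truthed motion data.

Axis convention (shared by every module): index order ``(x, y, z)`` with
``z`` the axial/depth axis, 0-based indices, FOV position referring to the
crop's minimum corner, and a positive shift moving the FOV in positive world
coordinates.  The FOV spans 5 mm x 5 mm x 3.5 mm over 32 voxels per axis, so
one voxel is (5/32, 5/32, 3.5/32) mm — exactly representable in binary
floating point, which keeps integer-voxel shifts exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "FOV_MM",
    "VOLUME_SHAPE",
    "MM_PER_VOXEL",
    "Calibration",
    "TextureParams",
    "Phantom",
    "PhantomSizeError",
    "OutOfBoundsError",
    "make_phantom",
    "acquire_volume",
    "check_volume",
]

#: physical extent of one acquired volume, mm
FOV_MM = (5.0, 5.0, 3.5)
#: voxel grid of one acquired volume
VOLUME_SHAPE = (32, 32, 32)
#: physical size of one voxel, mm (exact binary fractions)
MM_PER_VOXEL = tuple(f / n for f, n in zip(FOV_MM, VOLUME_SHAPE))


class PhantomSizeError(ValueError):
    """Phantom grid too small for the FOV plus the requested shift range."""


class OutOfBoundsError(ValueError):
    """A shifted FOV would leave the phantom; never silently zero-padded."""


@dataclass(frozen=True)
class Calibration:
    """Linear mapping between physical shifts (mm) and stepper-motor steps.

    The real rig calibrates galvo motor steps against image coordinates; here
    the mapping defaults to 1000 steps/mm per axis so labels can round-trip
    through motor-step space the same way.
    """

    mm_per_voxel: Tuple[float, float, float] = MM_PER_VOXEL
    motor_steps_per_mm: Tuple[float, float, float] = (1000.0, 1000.0, 1000.0)

    def __post_init__(self):
        if any(v <= 0 for v in self.mm_per_voxel) or any(
                v <= 0 for v in self.motor_steps_per_mm):
            raise ValueError("calibration entries must be strictly positive")

    def mm_to_steps(self, shift_mm) -> np.ndarray:
        return np.asarray(shift_mm, dtype=float) * np.asarray(self.motor_steps_per_mm)

    def steps_to_mm(self, steps) -> np.ndarray:
        return np.asarray(steps, dtype=float) / np.asarray(self.motor_steps_per_mm)

    def mm_to_voxels(self, shift_mm) -> np.ndarray:
        return np.asarray(shift_mm, dtype=float) / np.asarray(self.mm_per_voxel)


@dataclass(frozen=True)
class TextureParams:
    """Parameters of the synthetic tissue texture.

    surface_smoothness_mm : float
        Lateral correlation length of the random top-surface height field.
    surface_amplitude_mm : float
        Peak-to-trough scale (1 std) of the surface height variation.
    surface_depth_mm : float
        Mean depth of the tissue surface below the top of the grid.
    attenuation_per_mm : float
        Exponential intensity decay coefficient below the surface, emulating
        scattering attenuation of the OCT signal with depth.
    speckle_sigma : float
        Log-amplitude std of the multiplicative log-normal speckle; 0 turns
        speckle off.
    speckle_grain_mm : float
        Correlation length (band limit) of the speckle grain.
    macro_sigma : float
        Log-amplitude std of a coarse multiplicative heterogeneity field
        emulating tissue macrostructure (fiber bundles, fascia); 0 turns it
        off.  Counted as part of the speckle texture for normalization.
    macro_scale_mm : float
        Correlation length of the macrostructure field.
    background : float
        Constant amplitude above the surface (air), before normalization.
    """

    surface_smoothness_mm: float = 1.0
    surface_amplitude_mm: float = 0.35
    surface_depth_mm: float = 0.8
    attenuation_per_mm: float = 0.45
    speckle_sigma: float = 0.7
    speckle_grain_mm: float = 0.16
    macro_sigma: float = 0.6
    macro_scale_mm: float = 1.0
    background: float = 0.02


@dataclass
class Phantom:
    """Master scatter-amplitude grid from which shifted FOVs are sampled."""

    grid: np.ndarray
    pitch_mm: Tuple[float, float, float] = MM_PER_VOXEL
    origin_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0
    texture: TextureParams = field(default_factory=TextureParams)

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.grid.shape

    def max_shift_mm(self) -> np.ndarray:
        """Largest |shift| per axis (mm) for which the FOV stays inside."""
        margin_vox = (np.asarray(self.shape) - np.asarray(VOLUME_SHAPE)) // 2
        return margin_vox * np.asarray(self.pitch_mm)


def make_phantom(seed: int, grid_size: Sequence[int] = (96, 96, 96),
                 texture_params: TextureParams | None = None) -> Phantom:
    """Generate a deterministic speckle-textured tissue phantom.

    The amplitude field is a smooth random top surface, exponential depth
    attenuation below it and band-limited multiplicative log-normal speckle,
    normalized to [0, 1].  The grid must be at least 3x the FOV per axis so
    that shifted acquisitions have room to move.
    """
    grid_size = tuple(int(g) for g in grid_size)
    if any(g < 3 * n for g, n in zip(grid_size, VOLUME_SHAPE)):
        raise PhantomSizeError(
            f"grid {grid_size} smaller than 3x FOV {VOLUME_SHAPE}; no room "
            "for shifted acquisitions")
    tp = texture_params if texture_params is not None else TextureParams()
    pitch = np.asarray(MM_PER_VOXEL)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x0C7]))

    nx, ny, nz = grid_size
    # smooth random surface height (mm below grid top)
    sigma_lat = tp.surface_smoothness_mm / pitch[:2]
    h = rng.standard_normal((nx, ny))
    h = gaussian_filter(h, sigma=sigma_lat, mode="wrap")
    std = h.std()
    if std > 0 and tp.surface_amplitude_mm > 0:
        h = h / std * tp.surface_amplitude_mm
    else:
        h = np.zeros_like(h)
    h = tp.surface_depth_mm + h

    # depth profile: soft surface edge, exponential attenuation below
    z_mm = np.arange(nz) * pitch[2]
    depth = z_mm[None, None, :] - h[:, :, None]          # mm below surface
    edge_width = pitch[2]                                 # ~1 voxel soft edge
    surface = 1.0 / (1.0 + np.exp(-depth / (0.25 * edge_width)))
    profile = surface * np.exp(-tp.attenuation_per_mm * np.maximum(depth, 0.0))
    amp = tp.background + (1.0 - tp.background) * profile

    log_texture = np.zeros(grid_size)
    for sigma_amp, scale_mm in ((tp.speckle_sigma, tp.speckle_grain_mm),
                                (tp.macro_sigma, tp.macro_scale_mm)):
        if sigma_amp <= 0:
            continue
        g = rng.standard_normal(grid_size)
        g = gaussian_filter(g, sigma=scale_mm / pitch, mode="wrap")
        gstd = g.std()
        if gstd > 0:
            g = g / gstd
        log_texture += sigma_amp * g - 0.5 * sigma_amp ** 2
    if np.any(log_texture):
        below = depth > 0
        amp = np.where(below, amp * np.exp(log_texture), amp)

    amp = amp / amp.max()
    return Phantom(grid=amp.astype(np.float32), pitch_mm=tuple(pitch),
                   seed=int(seed), texture=tp)


def _reference_corner(phantom: Phantom) -> np.ndarray:
    """Index of the unshifted FOV's minimum corner (centred in the grid)."""
    return (np.asarray(phantom.shape) - np.asarray(VOLUME_SHAPE)) // 2


def acquire_volume(phantom: Phantom, shift_mm,
                   calibration: Calibration | None = None) -> np.ndarray:
    """Acquire the 32^3 FOV displaced by ``shift_mm`` (trilinear resampling).

    Raises :class:`OutOfBoundsError` if the shifted FOV leaves the phantom.
    """
    cal = calibration if calibration is not None else Calibration()
    shift_vox = np.asarray(shift_mm, dtype=float) / np.asarray(phantom.pitch_mm)
    pos = _reference_corner(phantom) + shift_vox

    base = np.floor(pos).astype(int)
    frac = pos - base
    # integer shifts resolve to frac == 0 exactly (pitches are binary fractions)
    hi_extent = np.where(frac > 0, 1, 0)
    if np.any(base < 0) or np.any(
            base + np.asarray(VOLUME_SHAPE) - 1 + hi_extent
            > np.asarray(phantom.shape) - 1):
        raise OutOfBoundsError(
            f"shift {np.asarray(shift_mm)} mm moves the FOV outside the "
            f"phantom (grid {phantom.shape}, max |shift| "
            f"{phantom.max_shift_mm()} mm)")

    n = np.asarray(VOLUME_SHAPE)
    cube = phantom.grid[base[0]:base[0] + n[0] + hi_extent[0],
                        base[1]:base[1] + n[1] + hi_extent[1],
                        base[2]:base[2] + n[2] + hi_extent[2]].astype(np.float64)
    out = np.zeros(VOLUME_SHAPE, dtype=np.float64)
    for dx in (0, 1):
        wx = frac[0] if dx else 1.0 - frac[0]
        if wx == 0.0:
            continue
        for dy in (0, 1):
            wy = frac[1] if dy else 1.0 - frac[1]
            if wy == 0.0:
                continue
            for dz in (0, 1):
                wz = frac[2] if dz else 1.0 - frac[2]
                if wz == 0.0:
                    continue
                out += (wx * wy * wz) * cube[dx:dx + n[0],
                                             dy:dy + n[1],
                                             dz:dz + n[2]]
    return out.astype(np.float32)


def check_volume(vol: np.ndarray) -> np.ndarray:
    """Validate the volume contract: shape 32^3, finite, values in [0, 1]."""
    vol = np.asarray(vol)
    if vol.shape != VOLUME_SHAPE:
        raise ValueError(f"volume shape {vol.shape} != {VOLUME_SHAPE}")
    if not np.all(np.isfinite(vol)):
        raise ValueError("volume contains non-finite values")
    if vol.min() < 0 or vol.max() > 1:
        raise ValueError("volume intensities outside [0, 1]")
    return vol
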