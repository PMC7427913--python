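"""CT volume container, coordinate mapping, trilinear sampling and HU-to-speed.

The CT image is the only patient-specific input to the phase-correction
pipeline: every collision point, surface normal and sound-speed estimate is
derived from its Hounsfield-unit (HU) grid. This module owns the voxel/world
geometry so that all downstream ray arithmetic can run in world millimetres.

Conventions
-----------
* Voxel index ``i`` (fractional allowed) maps to the world position
  ``origin + orientation @ (i * spacing)``; i.e. indices address voxel
  *centers* and the sampling domain is the convex hull of voxel centers.
* World coordinates are millimetres, sound speeds m/s, frequencies Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "CTVolume",
    "SpeedMap",
    "OutsideVolumeError",
    "sample_trilinear",
    "hu_to_speed",
    "read_nifti",
    "write_nifti",
]


class OutsideVolumeError(ValueError):
    """A sample point lies outside the hull of voxel centers."""


@dataclass
class CTVolume:
    """A 3-D grid of Hounsfield values with a rigid voxel-to-world mapping.

    Parameters
    ----------
    data:
        HU values, shape ``(nx, ny, nz)``.
    spacing:
        Per-axis voxel size in mm, all positive.
    origin:
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    orientation:
        3x3 matrix whose columns are the world directions of the voxel axes;
        must be orthonormal (a rotation, possibly with flips).
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"CTVolume requires a 3-D grid, got {self.data.ndim}-D")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(3, 3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.allclose(self.orientation.T @ self.orientation, np.eye(3), atol=1e-9):
            raise ValueError("orientation columns must be orthonormal")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("HU grid contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 homogeneous voxel-index -> world-mm affine."""
        a = np.eye(4)
        a[:3, :3] = self.orientation * self.spacing[None, :]
        a[:3, 3] = self.origin
        return a

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world mm coordinates to fractional voxel indices."""
        p = np.asarray(points, dtype=float)
        return ((p - self.origin) @ self.orientation) / self.spacing

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (fractional) voxel indices to world mm coordinates."""
        i = np.asarray(indices, dtype=float)
        return (i * self.spacing) @ self.orientation.T + self.origin

    def contains(self, points: np.ndarray) -> np.ndarray:
        """True where a world point lies within the hull of voxel centers."""
        v = self.world_to_voxel(points)
        hi = np.asarray(self.shape, dtype=float) - 1.0
        return np.all((v >= 0.0) & (v <= hi), axis=-1)


def sample_trilinear(vol: CTVolume, points: np.ndarray, *, outside: str = "error") -> np.ndarray:
    """Trilinear interpolation of the HU grid at world points.

    Parameters
    ----------
    vol:
        The CT volume.
    points:
        World coordinates, shape ``(3,)`` or ``(m, 3)``.
    outside:
        ``"error"`` raises :class:`OutsideVolumeError` for any point outside
        the hull of voxel centers; ``"water"`` substitutes 0 HU there, the
        convention used during ray marching (the transducer sits in water
        beyond the scanned block).

    Returns
    -------
    HU value(s) with the leading shape of ``points``.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    scalar = np.asarray(points).ndim == 1
    v = vol.world_to_voxel(p)
    hi = np.asarray(vol.shape, dtype=float) - 1.0
    inside = np.all((v >= 0.0) & (v <= hi), axis=-1)
    out = np.zeros(len(p))
    if outside == "error":
        if not np.all(inside):
            bad = p[~inside][0]
            raise OutsideVolumeError(f"point {bad} outside volume sampling domain")
    elif outside != "water":
        raise ValueError(f"unknown outside policy {outside!r}")
    if np.any(inside):
        data = vol.data
        if not np.issubdtype(data.dtype, np.floating):
            # cache the float view: integer grids would otherwise be copied
            # on every marching call
            data = getattr(vol, "_float_data", None)
            if data is None:
                data = vol.data.astype(np.float32)
                object.__setattr__(vol, "_float_data", data)
        out[inside] = ndimage.map_coordinates(data, v[inside].T, order=1, mode="nearest")
    return out[0] if scalar else out


@dataclass(frozen=True)
class SpeedMap:
    """Piecewise-linear Hounsfield-unit to longitudinal sound-speed mapping.

    The map is anchored at two points and clamped outside them: pure water
    (``hu_water``, default 0 HU) maps to ``c_water`` and dense cortical bone
    (``hu_bone``, default 1000 HU) maps to ``c_bone_max``. Defaults follow the
    convention of a 1480 m/s water path and a 2900 m/s cortical-bone ceiling.
    """

    c_water: float = 1480.0
    c_bone_max: float = 2900.0
    hu_water: float = 0.0
    hu_bone: float = 1000.0

    def __post_init__(self) -> None:
        if not (self.c_bone_max > self.c_water > 0):
            raise ValueError("require c_bone_max > c_water > 0")
        if not self.hu_bone > self.hu_water:
            raise ValueError("require hu_bone > hu_water")

    def to_dict(self) -> dict:
        return {
            "c_water": self.c_water,
            "c_bone_max": self.c_bone_max,
            "hu_water": self.hu_water,
            "hu_bone": self.hu_bone,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpeedMap":
        return cls(**d)


def hu_to_speed(m: SpeedMap, hu: np.ndarray | float) -> np.ndarray | float:
    """Sound speed (m/s) for Hounsfield value(s) under the linear clamped map."""
    h = np.asarray(hu, dtype=float)
    if not np.all(np.isfinite(h)):
        raise ValueError("non-finite HU value")
    t = np.clip((h - m.hu_water) / (m.hu_bone - m.hu_water), 0.0, 1.0)
    c = m.c_water + (m.c_bone_max - m.c_water) * t
    return float(c) if np.isscalar(hu) else c


def read_nifti(path) -> CTVolume:
    """Load a 3-D NIfTI-1 image as a :class:`CTVolume`.

    The image affine is decomposed into spacing (column norms), orientation
    (normalized columns) and origin. Only strictly 3-D images are accepted.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: non-3D image (ndim={data.ndim})")
    aff = np.asarray(img.affine, dtype=float)
    m = aff[:3, :3]
    spacing = np.linalg.norm(m, axis=0)
    if np.any(spacing <= 0):
        raise ValueError(f"{path}: degenerate affine (zero-length axis)")
    orientation = m / spacing[None, :]
    return CTVolume(data=data, spacing=spacing, origin=aff[:3, 3], orientation=orientation)


def write_nifti(vol: CTVolume, path) -> None:
    """Write a :class:`CTVolume` as NIfTI-1, preserving grid and affine."""
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.header.set_zooms(tuple(vol.spacing))
    nib.save(img, str(path))
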