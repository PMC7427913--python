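"""Transducer geometry, fiducial detection and rigid frame registration.

A hemispherical phased array and a CT scanner each carry their own coordinate
frame; the phase correction is only meaningful once the two are rigidly
aligned. Alignment uses corresponding fiducial markers: high-density spheres
embedded at known positions in the transducer's skull-fixing frame, detected
in the CT by thresholding plus a granulometric size filter, and matched by
index to their as-designed transducer-frame coordinates. The rigid transform
is the least-squares orthogonal-Procrustes solution via SVD of the centered
cross-covariance (Kabsch), with the determinant corrected to +1 so noise can
never produce a reflection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import CTVolume

__all__ = [
    "TransducerArray",
    "RigidTransform",
    "FiducialSet",
    "RegistrationResult",
    "NoFiducialsError",
    "make_hemisphere_array",
    "make_symmetric_array",
    "detect_fiducials",
    "register_svd",
    "apply_transform",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class NoFiducialsError(RuntimeError):
    """No connected component passed the fiducial size filter."""


@dataclass
class TransducerArray:
    """Element center positions of a phased-array transducer.

    ``elements`` are world positions in mm, one row per channel; ``f0`` is the
    driving frequency in Hz; ``geometric_focus`` is the common focal point of
    the physical geometry; ``active`` flags channels currently driven.
    """

    elements: np.ndarray
    f0: float = 650e3
    geometric_focus: np.ndarray = field(default_factory=lambda: np.zeros(3))
    active: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=float).reshape(-1, 3)
        self.geometric_focus = np.asarray(self.geometric_focus, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.elements)):
            raise ValueError("non-finite element coordinates")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if self.active is None:
            self.active = np.ones(len(self.elements), dtype=bool)
        self.active = np.asarray(self.active, dtype=bool).reshape(len(self.elements))

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "id": np.arange(self.n_elements),
                "x_mm": self.elements[:, 0],
                "y_mm": self.elements[:, 1],
                "z_mm": self.elements[:, 2],
            }
        )
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, f0: float = 650e3, geometric_focus=(0.0, 0.0, 0.0)) -> "TransducerArray":
        df = pd.read_csv(path)
        pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        return cls(elements=pts, f0=f0, geometric_focus=np.asarray(geometric_focus))


def make_hemisphere_array(
    n: int = 1024,
    radius: float = 150.0,
    cap_half_angle: float = 90.0,
    seed: int = 0,
    f0: float = 650e3,
    focus=(0.0, 0.0, 0.0),
) -> TransducerArray:
    """Generate a synthetic spherical-cap array focused at the sphere center.

    Elements are laid out on a Fibonacci spiral over a cap of half-angle
    ``cap_half_angle`` degrees about the +z axis, all at distance ``radius``
    from ``focus``. The layout is deterministic for a given ``seed`` (the seed
    rotates the spiral's starting azimuth, giving reproducible but distinct
    realizations). A stand-in for proprietary clinical element tables.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not (0.0 < cap_half_angle <= 90.0):
        raise ValueError("cap_half_angle must be in (0, 90] degrees")
    focus = np.asarray(focus, dtype=float).reshape(3)
    cos_cap = np.cos(np.deg2rad(cap_half_angle))
    if n == 1:
        dirs = np.array([[0.0, 0.0, 1.0]])
    else:
        i = np.arange(n)
        z = 1.0 - (1.0 - cos_cap) * (i + 0.5) / n
        phi = i * _GOLDEN_ANGLE + float(np.random.default_rng(seed).uniform(0, 2 * np.pi))
        s = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
        dirs = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    return TransducerArray(elements=focus + radius * dirs, f0=f0, geometric_focus=focus)


def make_symmetric_array(
    radius: float = 120.0,
    generator=(2.0, 3.0, 6.0),
    f0: float = 650e3,
    focus=(0.0, 0.0, 0.0),
) -> TransducerArray:
    """Array whose element directions form a signed-permutation orbit.

    All 48 images of ``generator`` under coordinate permutations and sign
    flips (the octahedral symmetry group of a cubic voxel lattice), placed at
    ``radius`` from ``focus``. Aimed at a phantom that shares the lattice
    symmetry (e.g. a concentric shell on an origin-centered grid), every
    element sees an exactly congruent discrete geometry — the reference
    configuration for symmetry validation of the tracing pipeline.
    """
    from itertools import permutations, product

    g = np.asarray(generator, dtype=float)
    if np.any(g == 0) or len(set(np.abs(g))) != 3:
        raise ValueError("generator must have three distinct nonzero magnitudes")
    dirs = []
    for perm in permutations(range(3)):
        for signs in product((1.0, -1.0), repeat=3):
            dirs.append(g[list(perm)] * signs)
    dirs = np.unique(np.round(np.asarray(dirs), 12), axis=0)
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    focus = np.asarray(focus, dtype=float)
    return TransducerArray(elements=focus + radius * dirs, f0=f0, geometric_focus=focus)


@dataclass
class RigidTransform:
    """Proper rigid motion ``p -> R @ p + t`` (rotation + translation, mm)."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        if not np.allclose(self.R.T @ self.R, np.eye(3), atol=1e-9):
            raise ValueError("R is not orthogonal")
        if not np.isclose(np.linalg.det(self.R), 1.0, atol=1e-9):
            raise ValueError("R is not a proper rotation (det != +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.R.T + self.t

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.t)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform applying ``other`` first, then ``self``."""
        return RigidTransform(self.R @ other.R, self.R @ other.t + self.t)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"R": self.R.tolist(), "T": self.t.tolist()}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["R"]), np.asarray(d["T"]))


def apply_transform(t: RigidTransform, p: np.ndarray) -> np.ndarray:
    """Apply a rigid transform to world point(s): returns ``R @ p + T``."""
    return t.apply(p)


@dataclass
class FiducialSet:
    """Labelled marker positions in one coordinate frame (mm)."""

    points: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.labels is None:
            self.labels = [f"F{i}" for i in range(len(self.points))]
        if len(self.labels) != len(self.points):
            raise ValueError("labels/points length mismatch")

    def __len__(self) -> int:
        return len(self.points)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "id": self.labels,
                "x_mm": self.points[:, 0],
                "y_mm": self.points[:, 1],
                "z_mm": self.points[:, 2],
            }
        )
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "FiducialSet":
        df = pd.read_csv(path)
        return cls(
            points=df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
            labels=[str(v) for v in df["id"]],
        )


def detect_fiducials(
    vol: CTVolume,
    hu_threshold: float = 2500.0,
    diameter_mm: float = 2.0,
    diameter_tolerance: float = 0.5,
) -> FiducialSet:
    """Locate marker spheres in a CT volume.

    Binarizes at ``hu_threshold`` (well above cortical bone), labels connected
    components, and keeps those whose volume-equivalent diameter lies within
    ``diameter_tolerance`` (fractional, default ±50%) of ``diameter_mm`` — a
    granulometric size filter that rejects both speckle and large metallic
    hardware. Returns intensity-weighted centroids in world mm, ordered along
    the first voxel axis for reproducibility.
    """
    mask = vol.data >= hu_threshold
    labels, n = ndimage.label(mask)
    if n == 0:
        raise NoFiducialsError("no fiducials found (no voxels above threshold)")
    idx = np.arange(1, n + 1)
    counts = ndimage.sum_labels(np.ones_like(labels, dtype=float), labels, idx)
    voxel_volume = float(np.prod(vol.spacing))
    d_eq = (6.0 * counts * voxel_volume / np.pi) ** (1.0 / 3.0)
    keep = np.abs(d_eq - diameter_mm) <= diameter_tolerance * diameter_mm
    if not np.any(keep):
        raise NoFiducialsError(
            f"no fiducials found ({n} components, none within "
            f"{diameter_tolerance:.0%} of {diameter_mm} mm)"
        )
    weights = np.where(mask, vol.data, 0.0)
    coms = ndimage.center_of_mass(weights, labels, idx[keep])
    world = vol.voxel_to_world(np.asarray(coms))
    order = np.lexsort((world[:, 2], world[:, 1], world[:, 0]))
    return FiducialSet(points=world[order])


@dataclass(frozen=True)
class RegistrationResult:
    transform: RigidTransform
    rms_mm: float


def register_svd(src: FiducialSet, dst: FiducialSet) -> RegistrationResult:
    """Least-squares rigid registration of corresponding point sets.

    Minimizes ``sum_i ||R @ src_i + T - dst_i||^2`` over proper rotations R and
    translations T: center both sets, form the cross-covariance
    ``H = sum (src_i - s̄)(dst_i - d̄)^T``, take ``H = U S V^T`` and set
    ``R = V diag(1, 1, det(V U^T)) U^T``, ``T = d̄ - R s̄``. Correspondence is
    by index. Requires K >= 3 non-collinear points.
    """
    a, b = src.points, dst.points
    if len(a) != len(b):
        raise ValueError(f"fiducial count mismatch: {len(a)} vs {len(b)}")
    if len(a) < 3:
        raise ValueError("registration needs at least 3 fiducials")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    # Collinear sets leave the rotation about the common axis unconstrained.
    if np.linalg.matrix_rank(a0, tol=1e-9 * max(1.0, np.abs(a0).max())) < 2:
        raise ValueError("degenerate (collinear) fiducial configuration")
    h = a0.T @ b0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cb - r @ ca
    xf = RigidTransform(r, t)
    res = xf.apply(a) - b
    rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return RegistrationResult(transform=xf, rms_mm=rms)
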