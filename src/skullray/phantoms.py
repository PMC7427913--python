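"""Parametric synthetic skull phantoms with closed-form path oracles.

Real skull CTs for transcranial ultrasound work are rarely shareable, so the
test bed is built on analytic phantoms: flat or tilted bone slabs, concentric
spherical shells (optionally with a low-HU cancellous diploë between two
cortical tables, reproducing the characteristic two-peak HU profile along a
transmitted ray), and a fiducial frame of small high-HU marker spheres. Every
phantom is defined in continuous world geometry; :func:`voxelize` samples it
onto a CT grid (voxel centers take the analytic layer HU, optionally with
seeded Gaussian noise), while :func:`analytic_path` computes exact
Snell-refracted segment lengths and the accumulated phase for supported
geometries without any voxel sampling — the independent oracle the voxel ray
tracer is validated against.

Default layer values: cortical 1200 HU (above the 700 HU bone threshold),
cancellous 300 HU (below it), water 0 HU, fiducials 3000 HU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np

from .raytrace import TotalInternalReflection, refract
from .volume import CTVolume, SpeedMap, hu_to_speed

__all__ = [
    "PhantomSpec",
    "AnalyticPath",
    "UnsupportedGeometryError",
    "voxelize",
    "analytic_path",
    "analytic_aberration",
]

_KINDS = {"flat_slab", "tilted_slab", "spherical_shell", "shell_with_cancellous", "fiducial_frame"}


class UnsupportedGeometryError(ValueError):
    """No closed-form path exists for this phantom/ray combination."""


@dataclass
class PhantomSpec:
    """Parametric phantom geometry; build via the class-method constructors."""

    kind: str
    extent: tuple = ((-60.0, 60.0), (-60.0, 60.0), (-60.0, 60.0))
    spacing_mm: float = 0.5
    hu_cortical: float = 1200.0
    hu_cancellous: float = 300.0
    hu_water: float = 0.0
    hu_fiducial: float = 3000.0
    noise_sigma: float = 0.0
    seed: int = 0
    # slab geometry
    plane_point: tuple | None = None
    normal: tuple | None = None  # unit vector from entry face into the slab
    thickness_mm: float | None = None
    tilt_deg: float = 0.0
    # shell geometry
    center: tuple = (0.0, 0.0, 0.0)
    radii: tuple | None = None  # ascending; 2 radii = one shell, 4 = two tables
    # fiducial geometry: list of (center xyz, diameter_mm, hu)
    spheres: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")

    # -- constructors -------------------------------------------------------

    @classmethod
    def slab(
        cls,
        interface_z: float = 40.0,
        thickness_mm: float = 6.0,
        tilt_deg: float = 0.0,
        facing: str = "down",
        **kw,
    ) -> "PhantomSpec":
        """A bone slab bounded by parallel planes.

        ``interface_z`` is where the entry plane crosses the z axis. With
        ``facing="down"`` the slab extends below the entry plane (for rays
        arriving from above, e.g. a +z transducer cap aiming at the origin);
        ``"up"`` extends it above (for rays travelling +z). ``tilt_deg``
        rotates the slab normal about the y axis.
        """
        if thickness_mm <= 0:
            raise ValueError("thickness must be positive")
        sign = -1.0 if facing == "down" else 1.0
        t = np.deg2rad(tilt_deg)
        m = (sign * np.sin(t), 0.0, sign * np.cos(t))
        kind = "flat_slab" if tilt_deg == 0 else "tilted_slab"
        kw.setdefault("extent", ((-60.0, 60.0), (-60.0, 60.0), (interface_z - thickness_mm - 20.0, interface_z + 20.0) if facing == "down" else (interface_z - 20.0, interface_z + thickness_mm + 20.0)))
        return cls(
            kind=kind,
            plane_point=(0.0, 0.0, interface_z),
            normal=m,
            thickness_mm=thickness_mm,
            tilt_deg=tilt_deg,
            **kw,
        )

    @classmethod
    def spherical_shell(cls, r_inner: float = 55.0, r_outer: float = 61.0, center=(0.0, 0.0, 0.0), **kw) -> "PhantomSpec":
        if not 0 < r_inner < r_outer:
            raise ValueError("require 0 < r_inner < r_outer")
        pad = 5.0
        kw.setdefault("extent", tuple((c - r_outer - pad, c + r_outer + pad) for c in center))
        return cls(kind="spherical_shell", center=tuple(center), radii=(r_inner, r_outer), **kw)

    @classmethod
    def shell_with_cancellous(cls, radii=(55.0, 57.0, 60.0, 62.0), center=(0.0, 0.0, 0.0), **kw) -> "PhantomSpec":
        """Two cortical tables (radii[0]..[1] and [2]..[3]) around a diploë."""
        r = tuple(float(x) for x in radii)
        if len(r) != 4 or not all(a < b for a, b in zip(r, r[1:])) or r[0] <= 0:
            raise ValueError("radii must be 4 ascending positive values")
        pad = 5.0
        kw.setdefault("extent", tuple((c - r[3] - pad, c + r[3] + pad) for c in center))
        return cls(kind="shell_with_cancellous", center=tuple(center), radii=r, **kw)

    @classmethod
    def fiducial_frame(cls, centers, diameter_mm: float = 2.0, extra_spheres=(), **kw) -> "PhantomSpec":
        """Marker spheres in water, plus optional extra (oversized) blobs."""
        spheres = tuple((tuple(map(float, c)), float(diameter_mm), None) for c in centers)
        spheres += tuple((tuple(map(float, c)), float(d), float(hu)) for c, d, hu in extra_spheres)
        return cls(kind="fiducial_frame", spheres=spheres, **kw)

    # -- geometry helpers ---------------------------------------------------

    @property
    def min_layer_mm(self) -> float:
        if self.kind in ("flat_slab", "tilted_slab"):
            return float(self.thickness_mm)
        if self.kind in ("spherical_shell", "shell_with_cancellous"):
            return float(min(b - a for a, b in zip(self.radii, self.radii[1:])))
        return float(min(d for _, d, _ in self.spheres))

    def hu_at(self, points: np.ndarray) -> np.ndarray:
        """Analytic HU at continuous world points, shape (..., 3)."""
        p = np.asarray(points, dtype=float)
        x, y, z = p[..., 0], p[..., 1], p[..., 2]
        return self._hu(x, y, z)

    def _hu(self, x, y, z) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        z = np.asarray(z, dtype=np.float32)
        shape = np.broadcast_shapes(x.shape, y.shape, z.shape)
        hu = np.full(shape, self.hu_water, dtype=np.float32)
        if self.kind in ("flat_slab", "tilted_slab"):
            m = np.asarray(self.normal)
            p0 = np.asarray(self.plane_point)
            depth = (x - p0[0]) * m[0] + (y - p0[1]) * m[1] + (z - p0[2]) * m[2]
            hu[(depth >= 0) & (depth < self.thickness_mm)] = self.hu_cortical
        elif self.kind in ("spherical_shell", "shell_with_cancellous"):
            c = np.asarray(self.center)
            r2 = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
            if self.kind == "spherical_shell":
                hu[(r2 >= self.radii[0] ** 2) & (r2 < self.radii[1] ** 2)] = self.hu_cortical
            else:
                r0, r1, r2_, r3 = self.radii
                hu[(r2 >= r0**2) & (r2 < r1**2)] = self.hu_cortical
                hu[(r2 >= r1**2) & (r2 < r2_**2)] = self.hu_cancellous
                hu[(r2 >= r2_**2) & (r2 < r3**2)] = self.hu_cortical
        else:
            for ctr, diam, hu_val in self.spheres:
                v = self.hu_fiducial if hu_val is None else hu_val
                r2 = (x - ctr[0]) ** 2 + (y - ctr[1]) ** 2 + (z - ctr[2]) ** 2
                hu[r2 <= (diam / 2.0) ** 2] = v
        return hu

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)

    @classmethod
    def from_json(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("extent", "plane_point", "normal", "center", "radii"):
            if d.get(key) is not None:
                d[key] = tuple(tuple(v) if isinstance(v, list) else v for v in d[key])
        d["spheres"] = tuple((tuple(c), dd, hh) for c, dd, hh in d.get("spheres", ()))
        return cls(**d)


def voxelize(spec: PhantomSpec) -> CTVolume:
    """Sample the analytic phantom onto a CT grid.

    Each voxel center takes the analytic layer HU at that point (no
    anti-aliasing); seeded Gaussian noise is added when ``noise_sigma > 0``.
    The grid is axis-aligned with isotropic ``spacing_mm``; an error is
    raised when the spacing cannot resolve the thinnest layer.
    """
    if spec.spacing_mm > spec.min_layer_mm:
        raise ValueError(
            f"undersampled layer: spacing {spec.spacing_mm} mm exceeds the "
            f"thinnest layer ({spec.min_layer_mm} mm)"
        )
    axes = []
    for lo, hi in spec.extent:
        n = int(np.floor((hi - lo) / spec.spacing_mm)) + 1
        axes.append(lo + spec.spacing_mm * np.arange(n))
    x, y, z = axes
    hu = spec._hu(x[:, None, None], y[None, :, None], z[None, None, :]).astype(np.float32)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sigma, size=hu.shape).astype(np.float32)
    origin = np.array([a[0] for a in axes])
    return CTVolume(data=hu, spacing=np.full(3, spec.spacing_mm), origin=origin)


@dataclass(frozen=True)
class AnalyticPath:
    """Exact continuous-geometry ray solution for a phantom."""

    d_w: float
    d_s: float
    d_b: float
    s1: np.ndarray
    s2: np.ndarray
    h_b: np.ndarray
    theta_I_ws: float
    theta_T_ws: float
    miss_distance: float
    c_ns: float
    phase: float  # total accumulated phase at f0, radians (unwrapped)


def analytic_path(
    spec: PhantomSpec,
    s0: np.ndarray,
    target: np.ndarray,
    speedmap: SpeedMap | None = None,
    f0: float = 650e3,
) -> AnalyticPath:
    """Closed-form Snell path and accumulated phase from ``s0`` toward ``target``.

    Supported geometries: slabs at any incidence below the critical angle, and
    concentric shells at radial (normal) incidence, i.e. the target at the
    shell center. Independent of any voxel grid.

    Raises
    ------
    TotalInternalReflection
        For slab incidence beyond the critical angle.
    UnsupportedGeometryError
        For geometries without a closed form.
    """
    speedmap = speedmap or SpeedMap()
    s0 = np.asarray(s0, dtype=float)
    target = np.asarray(target, dtype=float)
    h = target - s0
    h = h / np.linalg.norm(h)
    c_w = speedmap.c_water
    c_cort = float(hu_to_speed(speedmap, spec.hu_cortical))

    if spec.kind in ("flat_slab", "tilted_slab"):
        m = np.asarray(spec.normal, dtype=float)
        p0 = np.asarray(spec.plane_point, dtype=float)
        ch = float(np.dot(h, m))
        if ch <= 1e-12:
            raise UnsupportedGeometryError("ray does not enter the slab")
        if float(np.dot(s0 - p0, m)) >= 0:
            raise UnsupportedGeometryError("source not on the water side of the slab")
        d_w = float(np.dot(p0 - s0, m)) / ch
        s1 = s0 + d_w * h
        theta_i = float(np.arccos(np.clip(ch, -1.0, 1.0)))
        h_s = refract(h, -m, c_w, speedmap.c_bone_max)  # may raise TIR
        cos_t = float(np.dot(h_s, m))
        theta_t = float(np.arccos(np.clip(cos_t, -1.0, 1.0)))
        d_s = float(spec.thickness_mm) / cos_t
        s2 = s1 + d_s * h_s
        h_b = refract(h_s, -m, speedmap.c_bone_max, c_w)
        c_ns = c_cort
    elif spec.kind in ("spherical_shell", "shell_with_cancellous"):
        c = np.asarray(spec.center, dtype=float)
        if np.linalg.norm(target - c) > 1e-9:
            raise UnsupportedGeometryError("closed shell form requires the target at the center")
        r_src = float(np.linalg.norm(s0 - c))
        r_out = spec.radii[-1]
        r_in = spec.radii[0]
        if r_src <= r_out:
            raise UnsupportedGeometryError("source must lie outside the shell")
        d_w = r_src - r_out
        d_s = r_out - r_in
        s1 = s0 + d_w * h
        s2 = s0 + (d_w + d_s) * h
        h_b = h
        theta_i = theta_t = 0.0
        if spec.kind == "spherical_shell":
            c_ns = c_cort
        else:
            # Mean HU-derived speed over the two cortical tables only (the
            # diploë is excluded from the averaging, mirroring the phase
            # model); both tables share hu_cortical here.
            c_ns = c_cort
    else:
        raise UnsupportedGeometryError(f"no closed form for kind {spec.kind!r}")

    d_b = max(0.0, float(np.dot(target - s2, h_b)))
    closest = s2 + d_b * h_b
    miss = float(np.linalg.norm(target - closest))
    phase = 2.0 * np.pi * f0 * 1e-3 * (d_w / c_w + d_s / c_ns + d_b / c_w)
    return AnalyticPath(
        d_w=d_w,
        d_s=d_s,
        d_b=d_b,
        s1=s1,
        s2=s2,
        h_b=h_b,
        theta_I_ws=theta_i,
        theta_T_ws=theta_t,
        miss_distance=miss,
        c_ns=c_ns,
        phase=phase,
    )


def analytic_aberration(
    spec: PhantomSpec,
    array,
    target: np.ndarray,
    speedmap: SpeedMap | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-element excess phase through the phantom, and a transmit mask.

    Returns ``(delta_phi, transmits)``: ``delta_phi[n]`` is the analytic
    accumulated phase minus the homogeneous-water phase for element n (the
    phase-screen aberration used by the field simulator); ``transmits[n]`` is
    False where the slab incidence exceeds the critical angle (no transmitted
    ray, the element contributes nothing).
    """
    speedmap = speedmap or SpeedMap()
    target = np.asarray(target, dtype=float)
    n = array.n_elements
    delta = np.zeros(n)
    ok = np.ones(n, dtype=bool)
    for i in range(n):
        s0 = array.elements[i]
        water = 2.0 * np.pi * array.f0 * 1e-3 * float(np.linalg.norm(target - s0)) / speedmap.c_water
        try:
            ap = analytic_path(spec, s0, target, speedmap, array.f0)
        except TotalInternalReflection:
            ok[i] = False
            continue
        delta[i] = ap.phase - water
    return delta, ok
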