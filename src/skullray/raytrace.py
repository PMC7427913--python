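"""Per-element ray marching through the skull CT.

Each transducer element emits a single ray aimed at the commanded target. The
ray is marched in fixed steps (default 0.1 mm) through the trilinear-sampled
HU grid:

1. the first sample with HU >= tau_skull is the water->skull collision point;
2. a Zucker–Hummel 3x3x3 gradient estimates the surface normal there;
3. vector-form Snell refraction bends the ray into the bone;
4. the in-skull march records an HU profile and exits where HU drops back to
   <= tau_skull *after* the inner cortical table — a thin cancellous (diploë)
   dip below the threshold must not truncate the skull segment;
5. a second normal + refraction yields the in-brain direction, followed to
   the point of closest approach to the target.

Per-element failures (no skull crossing, incidence beyond the critical angle,
skull truncated at the grid edge) are recorded as a status on the
:class:`RayPath`, never raised, so a whole-array trace always completes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import CTVolume, SpeedMap, sample_trilinear

__all__ = [
    "RayStatus",
    "MarchConfig",
    "RayPath",
    "TotalInternalReflection",
    "DegenerateNormalError",
    "NoInnerBoundaryError",
    "zucker_hummel_kernels",
    "find_first_collision",
    "find_second_collision",
    "cortical_regions",
    "surface_normal",
    "refract",
    "trace_element",
    "trace_all",
    "paths_to_dataframe",
]


class RayStatus(str, enum.Enum):
    OK = "ok"
    NO_SKULL_HIT = "no_skull_hit"
    EXCEEDED_CRITICAL_ANGLE = "exceeded_critical_angle"
    TOTAL_INTERNAL_REFLECTION = "total_internal_reflection"
    LEFT_VOLUME = "left_volume"


class TotalInternalReflection(ValueError):
    """Snell's law admits no transmitted ray at this incidence."""


class DegenerateNormalError(ValueError):
    """The local HU gradient vanishes; no surface orientation is defined."""


class NoInnerBoundaryError(RuntimeError):
    """The in-skull march found no exit within the search length."""


@dataclass(frozen=True)
class MarchConfig:
    """Ray-marching parameters.

    ``step_mm`` is the sampling step along the ray; ``tau_skull`` the HU value
    separating water/soft tissue from bone; ``max_length_mm`` bounds every
    march; ``max_gap_mm`` is the longest sub-threshold gap bridged as
    cancellous bone between the two cortical tables (a gap longer than this is
    water, i.e. the skull has been exited); ``normal_flip`` keeps surface
    normals oriented against the incident ray; ``normal_smooth_sigma`` is the
    Gaussian pre-filter width, in voxels, applied to the local HU neighborhood
    before the gradient operators (0 disables smoothing).
    """

    step_mm: float = 0.1
    tau_skull: float = 700.0
    max_length_mm: float = 300.0
    max_gap_mm: float = 10.0
    normal_flip: bool = True
    normal_smooth_sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if self.max_length_mm <= 0:
            raise ValueError("max_length_mm must be positive")
        if self.max_gap_mm < 0:
            raise ValueError("max_gap_mm must be non-negative")
        if self.normal_smooth_sigma < 0:
            raise ValueError("normal_smooth_sigma must be non-negative")


@dataclass
class RayPath:
    """Geometry of one element's ray through water, skull and brain.

    Segment lengths are mm; angles radians; directions and normals unit
    vectors in world coordinates. Fields after a failure point are ``None``.
    """

    element_index: int
    status: RayStatus
    s0: np.ndarray
    s1: np.ndarray | None = None
    s2: np.ndarray | None = None
    h_w: np.ndarray | None = None
    h_s: np.ndarray | None = None
    h_b: np.ndarray | None = None
    n1: np.ndarray | None = None
    n2: np.ndarray | None = None
    theta_I_ws: float = np.nan
    theta_T_ws: float = np.nan
    theta_I_sb: float = np.nan
    theta_T_sb: float = np.nan
    d_w: float = np.nan
    d_s: float = np.nan
    d_b: float = np.nan
    miss_distance: float = np.nan
    hu_profile: np.ndarray = field(default_factory=lambda: np.empty(0))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


# ---------------------------------------------------------------------------
# Collision detection
# ---------------------------------------------------------------------------

def find_first_collision(
    vol: CTVolume, s0: np.ndarray, h: np.ndarray, cfg: MarchConfig
) -> tuple[np.ndarray, int] | None:
    """March from ``s0`` along unit direction ``h`` to the first bone sample.

    Samples ``s0 + k*step_mm*h`` for k = 1, 2, ... and returns
    ``(collision point, k)`` at the first sample with trilinear HU >=
    ``tau_skull`` (boundary-inclusive). Points outside the grid read as water
    (0 HU). Returns ``None`` if no sample reaches the threshold within
    ``max_length_mm``: whether bone exists beyond the scanned block is
    unknowable, so the caller decides how to treat a miss.
    """
    s0 = np.asarray(s0, dtype=float)
    h = np.asarray(h, dtype=float)
    n_steps = int(np.floor(cfg.max_length_mm / cfg.step_mm))
    # chunked march: early exit as soon as a chunk contains a crossing
    for start in range(1, n_steps + 1, _CHUNK):
        ks = np.arange(start, min(start + _CHUNK, n_steps + 1))
        pts = s0[None, :] + (cfg.step_mm * ks)[:, None] * h[None, :]
        hu = sample_trilinear(vol, pts, outside="water")
        hit = np.nonzero(hu >= cfg.tau_skull)[0]
        if len(hit):
            return pts[hit[0]], int(ks[hit[0]])
    return None


def find_second_collision(
    vol: CTVolume, s1: np.ndarray, h_s: np.ndarray, cfg: MarchConfig
) -> tuple[np.ndarray, np.ndarray]:
    """March through the skull from ``s1`` along ``h_s`` to the inner surface.

    Records the HU profile every ``step_mm`` and returns ``(s2, profile)``
    where ``s2`` is the first sample with HU <= ``tau_skull`` after the last
    cortical run — sub-threshold dips no longer than ``max_gap_mm`` are
    bridged as cancellous bone, so the exit lands on the inner cortical
    table's inner face. The profile covers the in-skull segment (s1 inclusive,
    s2 exclusive).

    Raises
    ------
    NoInnerBoundaryError
        If bone continues to ``max_length_mm``.
    OutsideVolumeError (via LEFT_VOLUME in :func:`trace_element`)
        Handled by the caller when the march leaves the grid mid-skull.
    """
    s1 = np.asarray(s1, dtype=float)
    h_s = np.asarray(h_s, dtype=float)
    n_steps = int(np.floor(cfg.max_length_mm / cfg.step_mm))
    gap_steps = max(1, int(np.ceil(cfg.max_gap_mm / cfg.step_mm)))
    hu = np.empty(0)
    next_k = 0
    while next_k <= n_steps:
        ks = np.arange(next_k, min(next_k + _CHUNK, n_steps + 1))
        pts = s1[None, :] + (cfg.step_mm * ks)[:, None] * h_s[None, :]
        hu = np.concatenate([hu, sample_trilinear(vol, pts, outside="water")])
        next_k = int(ks[-1]) + 1
        exit_idx = _scan_exit(hu >= cfg.tau_skull, gap_steps, complete=next_k > n_steps)
        if exit_idx is not None:
            s2 = s1 + cfg.step_mm * exit_idx * h_s
            if not vol.contains(s2[None, :])[0]:
                # Bone ran to the grid edge: the "exit" is an artifact of the
                # outside-is-water convention, not an anatomical boundary.
                raise NoInnerBoundaryError("skull truncated at volume boundary")
            return s2, hu[:exit_idx]
    raise NoInnerBoundaryError(f"no inner boundary within {cfg.max_length_mm} mm")


def _scan_exit(bone: np.ndarray, gap_steps: int, complete: bool) -> int | None:
    """First sub-threshold index after the last gap-bridged bone run.

    Walks runs of ``bone``, bridging False gaps shorter than ``gap_steps``
    (cancellous dips). Returns None when the available samples cannot yet
    prove the gap after the current run is water (unless ``complete``).
    """
    i = 0
    while True:
        nb = np.nonzero(~bone[i:])[0]
        if len(nb) == 0:
            return None  # still inside bone
        drop = i + int(nb[0])
        window = bone[drop : drop + gap_steps]
        rescue = np.nonzero(window)[0]
        if len(rescue):
            i = drop + int(rescue[0])
            continue
        if len(window) < gap_steps and not complete:
            return None  # gap not yet proven to be water
        return drop


def cortical_regions(hu_profile: np.ndarray, tau: float) -> tuple[np.ndarray, np.ndarray]:
    """Index ranges of the outer and inner cortical tables in an HU profile.

    The profile is split in half; the global HU maximum of each half is taken
    as that table's peak, and each region is the contiguous run of samples
    >= ``tau`` around its peak. With no cancellous dip the two regions
    coincide (possibly both spanning the whole profile).
    """
    p = np.asarray(hu_profile, dtype=float)
    if len(p) == 0:
        raise ValueError("empty HU profile")
    if np.all(p < tau):
        raise ValueError("no profile sample reaches tau; inconsistent with a collision")
    half = max(1, len(p) // 2)
    peaks = (int(np.argmax(p[:half])), half + int(np.argmax(p[half:])) if len(p) > half else 0)

    def _run(peak: int) -> np.ndarray:
        if p[peak] < tau:
            # Peak of this half is sub-threshold (profile shorter than two
            # tables): fall back to the nearest supra-threshold run.
            supra = np.nonzero(p >= tau)[0]
            peak = int(supra[np.argmin(np.abs(supra - peak))])
        lo = peak
        while lo > 0 and p[lo - 1] >= tau:
            lo -= 1
        hi = peak
        while hi < len(p) - 1 and p[hi + 1] >= tau:
            hi += 1
        return np.arange(lo, hi + 1)

    return _run(peaks[0]), _run(peaks[1])


# ---------------------------------------------------------------------------
# Surface normals (Zucker–Hummel 3x3x3 gradient operators)
# ---------------------------------------------------------------------------

def zucker_hummel_kernels() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The three 3x3x3 directional gradient kernels.

    Kernel value at integer offset (x, y, z) in {-1, 0, 1}^3 is
    ``x / sqrt(x^2 + y^2 + z^2)`` (resp. y, z); the 0/0 center is 0 by the
    operators' odd symmetry. Returned with index ``[x+1, y+1, z+1]``.
    """
    off = np.arange(-1, 2)
    x, y, z = np.meshgrid(off, off, off, indexing="ij")
    r = np.sqrt(x**2 + y**2 + z**2).astype(float)
    r[1, 1, 1] = 1.0  # center contributes 0 regardless
    return x / r, y / r, z / r


_KERNELS = zucker_hummel_kernels()
_CHUNK = 256  # marching samples per interpolation call


def surface_normal(
    vol: CTVolume,
    p: np.ndarray,
    toward: np.ndarray,
    flip: bool = True,
    smooth_sigma: float = 3.0,
) -> np.ndarray:
    """Unit surface normal at a collision point, oriented against the ray.

    Correlates the Zucker–Hummel kernels with the 3x3x3 HU neighborhood of
    the voxel nearest ``p`` (neighbors beyond the grid read as water), after
    an optional Gaussian pre-filter of ``smooth_sigma`` voxels over the local
    patch — a band-limiting step that suppresses the voxelization staircase
    of sharp interfaces without moving them. The index-space gradient is
    scaled by 1/spacing per axis and rotated into world coordinates, then
    flipped so that ``normal . toward < 0``.
    """
    p = np.asarray(p, dtype=float)
    toward = np.asarray(toward, dtype=float)
    c = np.rint(vol.world_to_voxel(p)).astype(int)
    nx, ny, nz = vol.shape
    r = 1 if smooth_sigma == 0 else int(np.ceil(3.0 * smooth_sigma)) + 1
    block = np.zeros((2 * r + 1,) * 3)
    lo = np.maximum(c - r, 0)
    hi = np.minimum(c + r + 1, [nx, ny, nz])
    if np.all(lo < hi):
        block[
            lo[0] - c[0] + r : hi[0] - c[0] + r,
            lo[1] - c[1] + r : hi[1] - c[1] + r,
            lo[2] - c[2] + r : hi[2] - c[2] + r,
        ] = vol.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    if smooth_sigma > 0:
        block = ndimage.gaussian_filter(block, smooth_sigma, mode="nearest")
    core = block[r - 1 : r + 2, r - 1 : r + 2, r - 1 : r + 2]
    g_index = np.array([float(np.sum(k * core)) for k in _KERNELS])
    g_world = vol.orientation @ (g_index / vol.spacing)
    mag = np.linalg.norm(g_world)
    if mag < 1e-12 * max(1.0, float(np.abs(block).max())):
        raise DegenerateNormalError(f"degenerate normal at {p} (flat HU neighborhood)")
    n = g_world / mag
    if flip and np.dot(n, toward) > 0:
        n = -n
    return n


# ---------------------------------------------------------------------------
# Refraction
# ---------------------------------------------------------------------------

def refract(h: np.ndarray, nrm: np.ndarray, c_in: float, c_out: float) -> np.ndarray:
    """Vector-form Snell refraction of unit direction ``h`` at a surface.

    ``nrm`` must be unit and oppose the incidence (``nrm . h < 0``). The
    transmitted direction lies in the plane of ``h`` and ``nrm`` with
    ``sin(theta_T) = (c_out/c_in) sin(theta_I)``.

    Raises
    ------
    TotalInternalReflection
        When ``(c_out/c_in) sin(theta_I) > 1`` (incidence beyond the critical
        angle of a slow->fast interface).
    """
    h = np.asarray(h, dtype=float)
    nrm = np.asarray(nrm, dtype=float)
    if abs(np.linalg.norm(h) - 1.0) > 1e-9 or abs(np.linalg.norm(nrm) - 1.0) > 1e-9:
        raise ValueError("h and nrm must be unit vectors")
    cos_i = -float(np.dot(nrm, h))
    if cos_i <= 0:
        raise ValueError("normal must oppose the incident direction (n . h < 0)")
    r = c_out / c_in
    sin_t_sq = r * r * (1.0 - cos_i * cos_i)
    if sin_t_sq > 1.0:
        raise TotalInternalReflection(
            f"sin(theta_T) = {np.sqrt(sin_t_sq):.4f} > 1 at c_ratio {r:.4f}"
        )
    cos_t = np.sqrt(1.0 - sin_t_sq)
    t = r * h + (r * cos_i - cos_t) * nrm
    return t / np.linalg.norm(t)


# ---------------------------------------------------------------------------
# Full per-element trace
# ---------------------------------------------------------------------------

def trace_element(
    vol: CTVolume,
    array,
    n: int,
    target: np.ndarray,
    cfg: MarchConfig | None = None,
    speeds: SpeedMap | None = None,
) -> RayPath:
    """Trace element ``n``'s ray to the target through the skull.

    Composes collision detection, normal estimation and refraction at both
    interfaces; fills a :class:`RayPath`. The aim direction is
    ``unit(target - s0)`` — the phased array steers electronically, so the
    ray is launched at the commanded target, not the geometric focus. The
    fixed water/maximum-bone speeds of ``speeds`` set both Snell ratios (the
    heterogeneous profile enters later, in the phase computation).

    A ray that crosses no bone keeps status ``no_skull_hit`` with its full
    water path length recorded in ``d_w`` (a legitimate water-window path);
    ``left_volume`` marks rays whose skull segment runs off the grid.
    """
    cfg = cfg or MarchConfig()
    speeds = speeds or SpeedMap()
    target = np.asarray(target, dtype=float)
    s0 = np.asarray(array.elements[n], dtype=float)
    h_w = _unit(target - s0)
    path = RayPath(element_index=n, status=RayStatus.OK, s0=s0, h_w=h_w)

    first = find_first_collision(vol, s0, h_w, cfg)
    if first is None:
        path.status = RayStatus.NO_SKULL_HIT
        path.d_w = float(np.linalg.norm(target - s0))
        path.d_s = 0.0
        path.d_b = 0.0
        path.miss_distance = 0.0
        return path
    s1, _ = first
    path.s1 = s1
    path.d_w = float(np.linalg.norm(s1 - s0))

    try:
        n1 = surface_normal(vol, s1, h_w, flip=cfg.normal_flip, smooth_sigma=cfg.normal_smooth_sigma)
    except DegenerateNormalError:
        path.status = RayStatus.LEFT_VOLUME
        return path
    path.n1 = n1
    cos_i = -float(np.dot(n1, h_w))
    path.theta_I_ws = float(np.arccos(np.clip(cos_i, -1.0, 1.0)))
    try:
        h_s = refract(h_w, n1, speeds.c_water, speeds.c_bone_max)
    except TotalInternalReflection:
        path.status = RayStatus.EXCEEDED_CRITICAL_ANGLE
        return path
    path.h_s = h_s
    path.theta_T_ws = float(
        np.arccos(np.clip(-np.dot(n1, h_s), -1.0, 1.0))
    )

    try:
        s2, profile = find_second_collision(vol, s1, h_s, cfg)
    except NoInnerBoundaryError:
        path.status = RayStatus.LEFT_VOLUME
        return path
    path.s2 = s2
    path.hu_profile = profile
    path.d_s = float(np.linalg.norm(s2 - s1))

    try:
        n2 = surface_normal(vol, s2, h_s, flip=cfg.normal_flip, smooth_sigma=cfg.normal_smooth_sigma)
    except DegenerateNormalError:
        path.status = RayStatus.LEFT_VOLUME
        return path
    path.n2 = n2
    cos_i2 = -float(np.dot(n2, h_s))
    path.theta_I_sb = float(np.arccos(np.clip(cos_i2, -1.0, 1.0)))
    try:
        h_b = refract(h_s, n2, speeds.c_bone_max, speeds.c_water)
    except TotalInternalReflection:
        path.status = RayStatus.TOTAL_INTERNAL_REFLECTION
        return path
    path.h_b = h_b
    path.theta_T_sb = float(np.arccos(np.clip(-np.dot(n2, h_b), -1.0, 1.0)))

    d_b = float(np.dot(target - s2, h_b))
    path.d_b = max(0.0, d_b)
    closest = s2 + path.d_b * h_b
    path.miss_distance = float(np.linalg.norm(target - closest))
    return path


def trace_all(
    vol: CTVolume,
    array,
    target: np.ndarray,
    cfg: MarchConfig | None = None,
    speeds: SpeedMap | None = None,
) -> list[RayPath]:
    """Trace every element of the array; per-element failures land in status."""
    return [trace_element(vol, array, n, target, cfg, speeds) for n in range(array.n_elements)]


def paths_to_dataframe(paths: list[RayPath]) -> pd.DataFrame:
    """Tabulate traced rays (angles in degrees, lengths mm) for CSV export."""
    rows = []
    for p in paths:
        rows.append(
            {
                "element": p.element_index,
                "status": p.status.value,
                "theta_I_ws_deg": np.degrees(p.theta_I_ws),
                "theta_T_ws_deg": np.degrees(p.theta_T_ws),
                "theta_I_sb_deg": np.degrees(p.theta_I_sb),
                "theta_T_sb_deg": np.degrees(p.theta_T_sb),
                "d_w_mm": p.d_w,
                "d_s_mm": p.d_s,
                "d_b_mm": p.d_b,
                "miss_distance_mm": p.miss_distance,
            }
        )
    return pd.DataFrame(rows)
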