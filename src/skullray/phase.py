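"""Aberration-phase computation and per-channel correction table.

The arrival phase of element n at the target accumulates over the three ray
segments (water, skull, brain):

    phi_n = 2*pi*f0 * (d_w/c_w + d_s/c_s_n + d_b/c_b)

with the in-skull speed ``c_s_n`` taken as the mean HU-derived speed over the
two *cortical* computation regions of the ray's HU profile — the cancellous
dip is excluded, since its porous structure is poorly represented by the
HU-speed map. The exported correction for an active channel is

    phi_corr_n = wrap(phi_ref_n - phi_n),   phi_ref_n = 2*pi*f0*|target-s0|/c_w

the phase offset that makes the aberrated arrival synchronous with a
homogeneous-water arrival, wrapped to [-pi, pi). Channels whose incidence
exceeds the critical angle (or whose skull segment leaves the grid) are
switched off and exported with phase 0.

Unit conventions: segment lengths arrive in mm and are converted to metres
here — this is the single mm/m conversion site in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import TransducerArray
from .raytrace import MarchConfig, RayPath, RayStatus, cortical_regions, trace_all
from .volume import CTVolume, SpeedMap, hu_to_speed

__all__ = [
    "PhaseCorrection",
    "UntreatableTargetError",
    "wrap_phase",
    "segment_speeds",
    "aberrated_phase",
    "reference_phase",
    "correction_phase",
    "build_correction",
    "export_correction",
    "read_correction",
]

_MM = 1e-3  # mm -> m


class UntreatableTargetError(RuntimeError):
    """Every channel was deactivated; no usable acoustic window exists."""


def wrap_phase(x):
    """Wrap phase(s) to the half-open interval [-pi, pi); pi maps to -pi."""
    return np.mod(np.asarray(x, dtype=float) + np.pi, 2.0 * np.pi) - np.pi


@dataclass
class PhaseCorrection:
    """Per-channel aberrated and correction phases for one sonication."""

    phi_aberr: np.ndarray
    phi_corr: np.ndarray
    active: np.ndarray
    f0: float
    c_nw: np.ndarray
    c_ns: np.ndarray
    c_nb: np.ndarray
    statuses: list[RayStatus]

    @property
    def n_active(self) -> int:
        return int(np.sum(self.active))

    def __len__(self) -> int:
        return len(self.phi_corr)


def segment_speeds(
    path: RayPath, speedmap: SpeedMap, regions: tuple[np.ndarray, np.ndarray] | None = None
) -> tuple[float, float, float]:
    """Segment-averaged sound speeds (c_w, c_s, c_b) for one ray, m/s.

    Water and brain speeds are both the water speed (the validation geometry
    is a water-filled ex-vivo skull; no brain tissue is present). The skull
    speed is the arithmetic mean of the HU-derived speed over the profile
    samples inside the two cortical regions only.
    """
    if path.status is not RayStatus.OK:
        raise ValueError(f"segment speeds require an ok ray, got {path.status.value}")
    if len(path.hu_profile) == 0:
        raise ValueError("ray carries no HU profile")
    if regions is None:
        raise ValueError("cortical regions required (from cortical_regions)")
    idx = np.union1d(regions[0], regions[1])
    if len(idx) == 0:
        raise ValueError("empty cortical regions")
    c_ns = float(np.mean(hu_to_speed(speedmap, path.hu_profile[idx])))
    return speedmap.c_water, c_ns, speedmap.c_water


def aberrated_phase(path: RayPath, speeds: tuple[float, float, float], f0: float) -> float:
    """Total accumulated (unwrapped) phase of one ray at the target, radians."""
    c_nw, c_ns, c_nb = speeds
    if c_nw <= 0 or c_nb <= 0 or (path.d_s > 0 and c_ns <= 0):
        raise ValueError("segment speeds must be positive")
    t = path.d_w * _MM / c_nw
    if path.d_s > 0:
        t += path.d_s * _MM / c_ns
    if path.d_b > 0:
        t += path.d_b * _MM / c_nb
    return 2.0 * np.pi * f0 * t


def reference_phase(s0: np.ndarray, target: np.ndarray, f0: float, c_water: float) -> float:
    """Phase of a straight homogeneous-water path from element to target."""
    d = float(np.linalg.norm(np.asarray(target, float) - np.asarray(s0, float)))
    return 2.0 * np.pi * f0 * d * _MM / c_water


def correction_phase(phi_aberr_n: float, phi_ref_n: float) -> float:
    """Excitation phase offset wrap(ref - aberrated) in [-pi, pi).

    Adding this offset to a channel makes its skull-delayed arrival coincide
    (mod 2*pi) with the homogeneous-water arrival shared by all channels, so
    the array refocuses at the target.
    """
    if not (np.isfinite(phi_aberr_n) and np.isfinite(phi_ref_n)):
        raise ValueError("phases must be finite")
    return float(wrap_phase(phi_ref_n - phi_aberr_n))


def build_correction(
    vol: CTVolume,
    array: TransducerArray,
    target: np.ndarray,
    cfg: MarchConfig | None = None,
    speedmap: SpeedMap | None = None,
) -> PhaseCorrection:
    """Trace all channels and assemble the per-channel correction table.

    Channels whose ray exceeds the critical angle, suffers total internal
    reflection or leaves the scanned grid mid-skull are deactivated (phase 0).
    A ray that meets no bone is a legitimate water-window path and stays
    active with a pure-water phase (correction exactly 0).
    """
    cfg = cfg or MarchConfig()
    speedmap = speedmap or SpeedMap()
    target = np.asarray(target, dtype=float)
    paths = trace_all(vol, array, target, cfg, speedmap)
    n = array.n_elements
    phi_ab = np.zeros(n)
    phi_corr = np.zeros(n)
    active = np.zeros(n, dtype=bool)
    c_nw = np.full(n, np.nan)
    c_ns = np.full(n, np.nan)
    c_nb = np.full(n, np.nan)
    statuses = []
    for p in paths:
        statuses.append(p.status)
        ref = reference_phase(p.s0, target, array.f0, speedmap.c_water)
        if p.status is RayStatus.OK:
            regions = cortical_regions(p.hu_profile, cfg.tau_skull)
            sp = segment_speeds(p, speedmap, regions)
            c_nw[p.element_index], c_ns[p.element_index], c_nb[p.element_index] = sp
            phi_ab[p.element_index] = aberrated_phase(p, sp, array.f0)
            phi_corr[p.element_index] = correction_phase(phi_ab[p.element_index], ref)
            active[p.element_index] = True
        elif p.status is RayStatus.NO_SKULL_HIT:
            sp = (speedmap.c_water, np.nan, speedmap.c_water)
            c_nw[p.element_index] = c_nb[p.element_index] = speedmap.c_water
            phi_ab[p.element_index] = aberrated_phase(p, (sp[0], 1.0, sp[2]), array.f0)
            phi_corr[p.element_index] = correction_phase(phi_ab[p.element_index], ref)
            active[p.element_index] = True
        # all other statuses: channel off, phase 0
    if not np.any(active):
        raise UntreatableTargetError("target untreatable: zero active channels")
    return PhaseCorrection(
        phi_aberr=phi_ab,
        phi_corr=phi_corr,
        active=active,
        f0=array.f0,
        c_nw=c_nw,
        c_ns=c_ns,
        c_nb=c_nb,
        statuses=statuses,
    )


def export_correction(pc: PhaseCorrection, path) -> None:
    """Write the per-channel table as CSV (channel, active, phase_rad, phase_deg)."""
    df = pd.DataFrame(
        {
            "channel": np.arange(len(pc)),
            "active": pc.active.astype(int),
            "phase_rad": np.where(pc.active, pc.phi_corr, 0.0),
            "phase_deg": np.degrees(np.where(pc.active, pc.phi_corr, 0.0)),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_correction(path) -> pd.DataFrame:
    """Read a correction CSV back, verifying channel-id integrity."""
    df = pd.read_csv(path)
    required = {"channel", "active", "phase_rad", "phase_deg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["channel"].duplicated().any():
        dupes = df.loc[df["channel"].duplicated(), "channel"].tolist()
        raise ValueError(f"{path}: duplicate channel ids {dupes}")
    return df
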