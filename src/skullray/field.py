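"""Monochromatic phased-summation field model and focal metrics.

An in-silico stand-in for hydrophone scanning: the complex pressure on a
sampling plane is the free-space Green's-function sum over active elements,

    field(x) = sum_n (1/r_n) * exp(i * (k_w r_n + phi_ab_n + phi_corr_n)),

with r_n the element-to-point distance and k_w the water wavenumber. Skull
aberration enters as a per-element phase screen (constant near the focus),
and the exported correction phases add on top — so a correction that exactly
conjugates the screen restores the free-field focus. Amplitude effects
(transmission loss, attenuation) are deliberately absent: the method under
test corrects phase only.

Default plane sampling follows hydrophone-scan practice: 0.25 mm step over a
10 mm x 10 mm window through the target, lateral (XY) or axial (XZ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import TransducerArray

__all__ = ["PlaneSpec", "FieldMap", "FocalMetrics", "make_plane", "simulate_field", "focal_metrics"]


@dataclass(frozen=True)
class PlaneSpec:
    """A rectangular sampling plane: origin (mm) plus two unit in-plane axes."""

    origin: np.ndarray
    axis_u: np.ndarray
    axis_v: np.ndarray
    extent_mm: float = 10.0
    step_mm: float = 0.25

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """World points (m, 3) and in-plane offsets (m, 2) covering the plane."""
        if self.step_mm <= 0 or self.extent_mm <= 0:
            raise ValueError("extent and step must be positive")
        half = self.extent_mm / 2.0
        n = int(round(self.extent_mm / self.step_mm)) + 1
        ticks = -half + self.step_mm * np.arange(n)
        uu, vv = np.meshgrid(ticks, ticks, indexing="ij")
        off = np.column_stack([uu.ravel(), vv.ravel()])
        pts = (
            np.asarray(self.origin)[None, :]
            + off[:, :1] * np.asarray(self.axis_u)[None, :]
            + off[:, 1:] * np.asarray(self.axis_v)[None, :]
        )
        return pts, off


def make_plane(target, orientation: str = "xy", extent_mm: float = 10.0, step_mm: float = 0.25) -> PlaneSpec:
    """Axis-aligned scan plane through the target ('xy' lateral, 'xz'/'yz' axial)."""
    axes = {
        "xy": ((1.0, 0, 0), (0, 1.0, 0)),
        "xz": ((1.0, 0, 0), (0, 0, 1.0)),
        "yz": ((0, 1.0, 0), (0, 0, 1.0)),
    }
    if orientation not in axes:
        raise ValueError(f"unknown plane orientation {orientation!r}")
    u, v = axes[orientation]
    return PlaneSpec(
        origin=np.asarray(target, dtype=float),
        axis_u=np.asarray(u),
        axis_v=np.asarray(v),
        extent_mm=extent_mm,
        step_mm=step_mm,
    )


@dataclass
class FieldMap:
    """Sampled complex field on a plane, with its magnitude peak."""

    plane: PlaneSpec
    points: np.ndarray
    complex_amplitude: np.ndarray
    shape: tuple[int, int]

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.complex_amplitude)

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.magnitude))

    @property
    def peak_location(self) -> np.ndarray:
        return self.points[self.peak_index]

    @property
    def peak_magnitude(self) -> float:
        return float(self.magnitude[self.peak_index])

    def magnitude_grid(self) -> np.ndarray:
        return self.magnitude.reshape(self.shape)


def simulate_field(
    array: TransducerArray,
    phases: np.ndarray | None,
    plane: PlaneSpec,
    aberration: np.ndarray | None = None,
    active: np.ndarray | None = None,
    amplitudes: np.ndarray | None = None,
    c_water: float = 1480.0,
) -> FieldMap:
    """Sum the monochromatic element contributions over a sampling plane.

    ``phases`` are the per-element excitation (correction) phases in radians
    (``None`` = all zero); ``aberration`` is the per-element phase screen the
    medium imposes (``None`` = free field); ``active`` masks silent channels;
    ``amplitudes`` scales each element (default 1). Deterministic.
    """
    n = array.n_elements
    phases = np.zeros(n) if phases is None else np.asarray(phases, dtype=float)
    aberr = np.zeros(n) if aberration is None else np.asarray(aberration, dtype=float)
    act = array.active if active is None else np.asarray(active, dtype=bool)
    amp = np.ones(n) if amplitudes is None else np.asarray(amplitudes, dtype=float)
    if not (len(phases) == len(aberr) == len(act) == len(amp) == n):
        raise ValueError("per-element arrays must match the element count")
    pts, _ = plane.grid()
    k_w = 2.0 * np.pi * array.f0 / (c_water * 1e3)  # rad per mm
    el = array.elements[act]
    r = np.linalg.norm(pts[:, None, :] - el[None, :, :], axis=2)  # (m, n_act) mm
    if np.any(r <= 0):
        raise ValueError("field point coincides with an element")
    psi = k_w * r + (aberr[act] + phases[act])[None, :]
    fld = np.sum(amp[act][None, :] / r * np.exp(1j * psi), axis=1)
    side = int(round(plane.extent_mm / plane.step_mm)) + 1
    return FieldMap(plane=plane, points=pts, complex_amplitude=fld, shape=(side, side))


@dataclass(frozen=True)
class FocalMetrics:
    """Focal-spot quality: shifts from the intended target (mm) and gain (%)."""

    shift_corrected_mm: float
    shift_uncorrected_mm: float
    shift_free_mm: float
    peak_corrected: float
    peak_uncorrected: float
    peak_free: float
    gain_percent: float

    def to_dict(self) -> dict:
        return {
            "shift_corrected_mm": self.shift_corrected_mm,
            "shift_uncorrected_mm": self.shift_uncorrected_mm,
            "shift_free_mm": self.shift_free_mm,
            "peak_corrected": self.peak_corrected,
            "peak_uncorrected": self.peak_uncorrected,
            "peak_free": self.peak_free,
            "gain_percent": self.gain_percent,
        }


def focal_metrics(
    map_corrected: FieldMap, map_uncorrected: FieldMap, map_free: FieldMap, target
) -> FocalMetrics:
    """Focal shift per condition and corrected/uncorrected peak gain.

    ``gain_percent = 100 * peak_corrected / peak_uncorrected``; the free-field
    peak is reported alongside as the attainable ceiling.
    """
    t = np.asarray(target, dtype=float)
    for m in (map_corrected, map_uncorrected, map_free):
        if len(m.points) == 0:
            raise ValueError("empty field map")
    return FocalMetrics(
        shift_corrected_mm=float(np.linalg.norm(map_corrected.peak_location - t)),
        shift_uncorrected_mm=float(np.linalg.norm(map_uncorrected.peak_location - t)),
        shift_free_mm=float(np.linalg.norm(map_free.peak_location - t)),
        peak_corrected=map_corrected.peak_magnitude,
        peak_uncorrected=map_uncorrected.peak_magnitude,
        peak_free=map_free.peak_magnitude,
        gain_percent=100.0 * map_corrected.peak_magnitude / map_uncorrected.peak_magnitude,
    )
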