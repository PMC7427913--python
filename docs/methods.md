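# Methods

## Model and assumptions

`skullray` treats each transducer channel's acoustic path as a single
geometric ray refracted at two interfaces: water→skull and skull→brain. The
underlying assumptions are those of linear, longitudinal-mode propagation in
fluid-like media: no shear conversion in bone, no multiple reflections, no
nonlinear effects, and no amplitude modelling (transmission loss and
attenuation are ignored; only the arrival *phase* is corrected). The skull is
characterized entirely by its CT Hounsfield grid; brain-side tissue is
assigned the water speed, matching the water-filled ex-vivo bench geometry
the method targets.

The per-channel aberrated phase is the accumulated travel time over the
three segments (water, skull, brain) times 2π f₀. The correction exported
for an active channel is wrap(∅_ref − ∅_n) with ∅_ref the straight
homogeneous-water phase to the target; adding it to the channel's excitation
makes all arrivals synchronous at the target. This reference/sign convention
is chosen because it is physically required for refocusing and is verified
end-to-end by the field module; the clinical counterpart's internal
convention is not public.

## Parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| `f0` | 650e3 | Hz | driving frequency |
| `tau_skull` | 700 | HU | bone threshold for collision detection |
| `step_mm` | 0.1 | mm | ray-marching step; localization error ≤ one step |
| `max_length_mm` | 300 | mm | march budget per segment |
| `max_gap_mm` | 10 | mm | longest sub-threshold gap bridged as cancellous bone |
| `normal_smooth_sigma` | 3.0 | voxels | Gaussian pre-filter before the gradient operators |
| `c_water` | 1480 | m/s | water/brain sound speed |
| `c_bone_max` | 2900 | m/s | dense cortical bone speed; also both Snell ratios |
| `hu_water`, `hu_bone` | 0, 1000 | HU | anchors of the HU→speed map |

The HU→speed mapping is a linear two-point map clamped to
[c_water, c_bone_max]: published CT-to-speed calibrations vary, so the map is
a configurable object (`SpeedMap`) anchored so that water (0 HU) gives
1480 m/s and dense cortical bone (≥1000 HU) gives 2900 m/s. It is a
documented stand-in, not a calibration claim.

Both refraction computations use the fixed c_bone_max for the Snell ratio:
at collision time the tracer has no estimate of the local bone speed yet.
The heterogeneous profile enters afterwards, in the phase integral, as the
mean HU-derived speed over the two *cortical* computation regions of the
in-skull HU profile — the cancellous diploë, whose porosity the HU-speed map
represents poorly, is excluded from the average. The two regions are found as
the contiguous supra-threshold runs around the HU maximum of each half of
the profile; for monotone or single-peak profiles both regions collapse onto
the same run (whole-profile fallback).

## Ray marching details

Marching uses fixed steps with trilinear interpolation; samples outside the
grid read as water (0 HU), because elements legitimately sit outside the
scanned block. Entry is the first sample ≥ τ (inclusive), exit the first
sample ≤ τ after the last bridged cortical run. `max_gap_mm` (10 mm,
generous for human diploë) is the scale that distinguishes a cancellous dip
from genuine water beyond the skull; without such a scale the two are
formally indistinguishable from the profile alone. A ray that crosses no
bone keeps its full water path and stays active (a water-window path is
legitimate and its correction is exactly zero); a ray whose skull segment
runs off the grid is deactivated (`left_volume`) since its true exit is
unknowable, and the same status is used when no inner boundary is found
within the march budget. The in-brain segment ends at the point of closest
approach to the target, clamped to non-negative length; the residual
`miss_distance` is recorded per ray.

## Surface normals

Normals come from the Zucker–Hummel 3×3×3 directional gradient operators
(kernel value x/√(x²+y²+z²) per axis, center 0 by odd symmetry), applied at
the voxel nearest the collision point. The operators assume band-limited
data; on hard synthetic interfaces (this package's phantoms are voxelized
without anti-aliasing) the staircase makes raw 3×3×3 gradients err by up to
~16° on a sphere. A Gaussian pre-filter over the local patch
(`normal_smooth_sigma`, default 3 voxels) restores band-limitation without
moving the interface: measured worst-case error on 500 random shell surface
points is ~3.6° at 0.5 mm voxels, and flat axis-aligned interfaces remain
exact by symmetry. The index-space gradient is divided by the per-axis voxel
size and rotated by the volume's orientation matrix, so anisotropic or
oblique volumes produce correct world-space normals. The normal is always
flipped to oppose the incident ray, since the raw gradient points up-HU
(into bone at entry, out of bone at exit).

## Registration

Fiducial detection binarizes well above bone HU (default 2500), labels
connected components, and applies a granulometric size filter implemented as
a volume-equivalent-diameter band (±50% of the nominal 2 mm marker
diameter), rejecting both speckle and large hardware; centroids are
intensity-weighted. The rigid estimate is the standard orthogonal-Procrustes
solution: center both point sets, SVD of the cross-covariance, determinant
correction to exclude reflections, translation from the rotated centroids.
Correspondence is by index; automatic matching is out of scope. The RMS
residual is returned as the registration quality metric.

## Synthetic phantoms and what they do (not) show

The phantom generator emulates the geometry that drives skull aberration:
a high-HU cortical shell (1200 HU), an optional sub-threshold cancellous
layer (300 HU) producing the characteristic two-peak HU profile, water
elsewhere (0 HU), fiducial spheres at 3000 HU, and optional seeded Gaussian
HU noise. Boundary voxels take the analytic layer HU of their center — no
partial-volume averaging — so phantom interfaces are *harder* than real CT
edges; this is deliberately conservative for the normal estimator but means
voxelization staircase effects are larger than in clinical data. Slabs and
concentric shells admit closed-form Snell paths and phases
(`analytic_path`), computed in continuous geometry independent of any grid;
these serve as oracles for the voxel tracer. What passing tests show:
geometric and phase consistency of the discrete pipeline with exact
refraction theory, and in-silico refocusing. What they do not show: fidelity
to real skulls (heterogeneous speeds, rough surfaces, shear conversion) or
hydrophone-level absolute pressures.

Two validation configurations exploit lattice geometry deliberately. The
oracle-equivalence check realizes oblique incidence by rotating the *array*
about an axis-aligned slab: physically identical angles, but interfaces stay
exact lattice planes, so the measured error isolates the marching and
refraction machinery from voxelization staircase (with a tilted slab the
staircase contribution alone is several times the marching error and scales
with voxel size, ~0.2–0.4 rad at 0.25 mm voxels — a separate test covers
that regime at its appropriate tolerance). The symmetry check uses element
directions forming signed-permutation orbits of the cubic lattice, for which
every element sees an exactly congruent discrete geometry; correction
phases then agree to floating-point precision, demonstrating that no
direction-dependent asymmetry is introduced by the pipeline itself. With
generic (Fibonacci) directions the same phantom shows a ~0.45 rad spread at
0.5 mm voxels, which is voxelization jitter, not method error.

## Field model

The field simulator is a monochromatic free-space Green's-function sum,
1/r amplitude and k·r phase per element, with skull aberration applied as a
per-element phase screen (constant near the focus). The screen approximation
makes exact conjugate cancellation algebraic — a correction equal to the
negated screen restores the free field identically — which is the property
the end-to-end tests rely on. It neglects the field-point dependence of the
skull delay across the scan window (second-order in the ~mm window used
here) and all amplitude effects. Default scan sampling is 0.25 mm over a
10 mm × 10 mm plane through the target, lateral (XY) or axial (XZ).

## Problem sizes and numerics

Validation runs use arrays of 48–256 elements, slab grids at 0.1–0.5 mm
voxels and shells at 0.5 mm (roughly 5–60 M voxels), marching steps of
0.1 mm (default) and 0.02 mm (fine); these sizes keep the full suite and the
acceptance script in the minutes range on a single core while leaving the
measured tolerances limited by the method, not the budget. Ties at the
threshold are inclusive (≥ τ entry, ≤ τ exit) as a fixed convention. Phase
wrapping is half-open [−π, π) with π mapping to −π. Degenerate cases are
explicit errors: zero-gradient normals, collinear fiducials, empty cortical
regions, a target behind the skull exit (clamped to zero brain path with the
miss recorded).

## Known limitations

Single ray per element (no bundle averaging over surface roughness); no
shear-mode or multiply-reflected rays; no refraction at internal
cortical/cancellous boundaries; no amplitude or apodization correction; the
HU→speed map is an uncalibrated linear stand-in; phantoms are piecewise
constant and cannot represent real trabecular texture.
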