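"""Ray marching, HU-profile analysis, surface normals and refraction."""

import numpy as np
import pytest

from skullray import (
    CTVolume,
    DegenerateNormalError,
    MarchConfig,
    NoInnerBoundaryError,
    PhantomSpec,
    RayStatus,
    SpeedMap,
    TotalInternalReflection,
    TransducerArray,
    cortical_regions,
    find_first_collision,
    find_second_collision,
    refract,
    sample_trilinear,
    surface_normal,
    trace_all,
    trace_element,
    voxelize,
    zucker_hummel_kernels,
)

C_W, C_S = 1480.0, 2900.0
CRITICAL_DEG = np.degrees(np.arcsin(C_W / C_S))  # ~30.69


class TestKernels:
    def test_directional_kernel_values(self):
        kx, ky, kz = zucker_hummel_kernels()
        # value at offset (x,y,z) is x/sqrt(x^2+y^2+z^2); center is 0
        assert kx[2, 1, 1] == pytest.approx(1.0)
        assert kx[2, 2, 2] == pytest.approx(1.0 / np.sqrt(3.0))
        assert np.all(kx[1, :, :] == 0.0)
        assert kx[1, 1, 1] == 0.0 and ky[1, 1, 1] == 0.0 and kz[1, 1, 1] == 0.0
        # odd symmetry and axis interchange
        assert np.allclose(kx, -kx[::-1, :, :])
        assert np.allclose(ky, np.transpose(kx, (1, 0, 2)))


class TestFirstCollision:
    def test_flat_interface_localized_within_one_step(self, slab_up_vol):
        cfg = MarchConfig(max_length_mm=120.0)
        hit = find_first_collision(slab_up_vol, np.zeros(3), np.array([0.0, 0.0, 1.0]), cfg)
        assert hit is not None
        s1, steps = hit
        assert 80.0 - 0.3 <= s1[2] <= 80.0 + 0.1  # trilinear onset just below the bone plane
        assert steps == pytest.approx(s1[2] / 0.1, abs=1)

    def test_miss_returns_none(self, slab_up_vol):
        cfg = MarchConfig(max_length_mm=120.0)
        assert find_first_collision(slab_up_vol, np.zeros(3), np.array([0.0, 0.0, -1.0]), cfg) is None

    def test_threshold_is_inclusive(self):
        vol = CTVolume(np.full((20, 20, 20), 700.0), spacing=(1.0, 1.0, 1.0))
        cfg = MarchConfig(max_length_mm=30.0)
        hit = find_first_collision(vol, np.array([-5.0, 5.0, 5.0]), np.array([1.0, 0.0, 0.0]), cfg)
        assert hit is not None
        assert 0.0 <= hit[0][0] <= 0.1

    def test_halving_step_never_degrades_localization(self, slab_up_vol):
        # error measured against the trilinear isosurface crossing found by
        # bisection (the quantity the march discretizes)
        rng = np.random.default_rng(9)
        cfg1 = MarchConfig(step_mm=0.1, max_length_mm=130.0)
        cfg2 = MarchConfig(step_mm=0.05, max_length_mm=130.0)
        for _ in range(20):
            h = np.array([rng.uniform(-0.1, 0.1), rng.uniform(-0.1, 0.1), 1.0])
            h /= np.linalg.norm(h)
            s0 = np.array([rng.uniform(-3, 3), rng.uniform(-3, 3), 0.0])
            for cfg_a, cfg_b in [(cfg1, cfg2)]:
                hits = []
                for cfg in (cfg_a, cfg_b):
                    s1, k = find_first_collision(slab_up_vol, s0, h, cfg)
                    t_hi = cfg.step_mm * k
                    t_lo = t_hi - cfg.step_mm
                    for _ in range(60):  # bisection oracle for the crossing
                        mid = 0.5 * (t_lo + t_hi)
                        v = sample_trilinear(slab_up_vol, s0 + mid * h, outside="water")
                        if v >= cfg.tau_skull:
                            t_hi = mid
                        else:
                            t_lo = mid
                    hits.append(cfg.step_mm * k - t_hi)
                err_coarse, err_fine = hits
                assert -1e-9 <= err_fine <= err_coarse + 1e-9


class TestSecondCollision:
    def test_homogeneous_slab_thickness(self, slab_up_vol):
        cfg = MarchConfig(max_length_mm=120.0)
        h = np.array([0.0, 0.0, 1.0])
        s1, _ = find_first_collision(slab_up_vol, np.zeros(3), h, cfg)
        s2, profile = find_second_collision(slab_up_vol, s1, h, cfg)
        d_s = np.linalg.norm(s2 - s1)
        assert d_s == pytest.approx(6.0, abs=0.35)
        assert len(profile) == pytest.approx(d_s / cfg.step_mm, abs=1.5)

    def test_cancellous_dip_is_bridged(self, shell_cc_vol):
        # radial ray: the exit must land on the inner table's inner face
        # (r=50), not at the sub-threshold diploe between r=52 and r=55
        cfg = MarchConfig(max_length_mm=200.0)
        h = np.array([0.0, 0.0, -1.0])
        s1, _ = find_first_collision(shell_cc_vol, np.array([0.0, 0.0, 90.0]), h, cfg)
        s2, profile = find_second_collision(shell_cc_vol, s1, h, cfg)
        d_s = np.linalg.norm(s2 - s1)
        assert d_s == pytest.approx(7.0, abs=0.4)
        assert profile.min() < cfg.tau_skull  # the dip is inside the segment

    def test_unbounded_bone_raises(self, slab_up_vol):
        cfg = MarchConfig(max_length_mm=3.0)
        h = np.array([0.0, 0.0, 1.0])
        s1, _ = find_first_collision(slab_up_vol, np.zeros(3), h, MarchConfig(max_length_mm=120.0))
        with pytest.raises(NoInnerBoundaryError):
            find_second_collision(slab_up_vol, s1, h, cfg)


class TestCorticalRegions:
    def test_two_peak_profile(self):
        profile = np.array([900.0, 1200.0, 300.0, 300.0, 1100.0, 800.0])
        outer, inner = cortical_regions(profile, tau=700.0)
        assert list(outer) == [0, 1]
        assert list(inner) == [4, 5]

    def test_single_peak_spans_whole_profile(self):
        profile = np.array([800.0, 900.0, 1000.0, 1100.0])
        outer, inner = cortical_regions(profile, tau=700.0)
        assert list(outer) == [0, 1, 2, 3]
        assert list(inner) == [0, 1, 2, 3]

    def test_singleton_profile(self):
        outer, inner = cortical_regions(np.array([750.0]), tau=700.0)
        assert list(outer) == [0] and list(inner) == [0]

    def test_all_subthreshold_raises(self):
        with pytest.raises(ValueError):
            cortical_regions(np.array([100.0, 200.0]), tau=700.0)


class TestSurfaceNormal:
    def test_flat_interface_axis_aligned(self, slab_up_vol):
        p = np.array([0.0, 0.0, 80.0])
        n = surface_normal(slab_up_vol, p, toward=np.array([0.0, 0.0, 1.0]))
        assert np.allclose(n, [0.0, 0.0, -1.0], atol=1e-9)

    def test_flat_region_degenerate(self):
        vol = CTVolume(np.full((31, 31, 31), 1000.0), spacing=(1.0, 1.0, 1.0))
        with pytest.raises(DegenerateNormalError):
            surface_normal(vol, np.array([15.0, 15.0, 15.0]), np.array([0.0, 0.0, 1.0]))

    def test_invariant_under_constant_hu_shift(self, slab_up_spec, slab_up_vol):
        p = np.array([0.5, -0.5, 80.0])
        toward = np.array([0.0, 0.0, 1.0])
        n1 = surface_normal(slab_up_vol, p, toward)
        shifted = CTVolume(
            slab_up_vol.data + 300.0,
            spacing=slab_up_vol.spacing,
            origin=slab_up_vol.origin,
            orientation=slab_up_vol.orientation,
        )
        n2 = surface_normal(shifted, p, toward)
        assert np.linalg.norm(n1 - n2) <= 1e-6


class TestRefract:
    def test_normal_incidence_passes_straight(self):
        h = np.array([0.0, 0.0, -1.0])
        t = refract(h, -h * -1.0 * -1.0, C_W, C_S)  # normal = +z opposes h
        assert np.allclose(t, h, atol=1e-12)

    def test_twenty_degree_incidence(self):
        ti = np.deg2rad(20.0)
        h = np.array([np.sin(ti), 0.0, -np.cos(ti)])
        nrm = np.array([0.0, 0.0, 1.0])
        t = refract(h, nrm, C_W, C_S)
        theta_t = np.degrees(np.arccos(-np.dot(nrm, t)))
        assert theta_t == pytest.approx(np.degrees(np.arcsin(C_S / C_W * np.sin(ti))), abs=1e-9)
        assert theta_t == pytest.approx(42.08, abs=0.01)

    def test_beyond_critical_angle_raises(self):
        ti = np.deg2rad(35.0)
        h = np.array([np.sin(ti), 0.0, -np.cos(ti)])
        with pytest.raises(TotalInternalReflection):
            refract(h, np.array([0.0, 0.0, 1.0]), C_W, C_S)

    def test_equal_speeds_identity_for_any_incidence(self):
        rng = np.random.default_rng(12)
        nrm = np.array([0.0, 0.0, 1.0])
        for _ in range(50):
            ti = rng.uniform(0.0, np.deg2rad(89.0))
            phi = rng.uniform(0, 2 * np.pi)
            h = np.array([np.sin(ti) * np.cos(phi), np.sin(ti) * np.sin(phi), -np.cos(ti)])
            t = refract(h, nrm, 1540.0, 1540.0)
            assert np.allclose(t, h, atol=1e-12)

    def test_snell_ratio_holds_for_random_incidence(self):
        rng = np.random.default_rng(13)
        nrm = np.array([0.0, 0.0, 1.0])
        for _ in range(50):
            ti = rng.uniform(0.0, np.arcsin(C_W / C_S) * 0.98)
            h = np.array([np.sin(ti), 0.0, -np.cos(ti)])
            t = refract(h, nrm, C_W, C_S)
            st = np.linalg.norm(np.cross(nrm, t))
            assert st == pytest.approx(C_S / C_W * np.sin(ti), abs=1e-12)

    def test_rejects_misoriented_normal(self):
        h = np.array([0.0, 0.0, -1.0])
        with pytest.raises(ValueError, match="oppose"):
            refract(h, np.array([0.0, 0.0, -1.0]), C_W, C_S)


class TestTraceElement:
    def test_collinear_target_beyond_slab(self, slab_up_vol):
        arr = TransducerArray(elements=[[0.0, 0.0, 0.0]], geometric_focus=(0.0, 0.0, 120.0))
        target = np.array([0.0, 0.0, 120.0])
        p = trace_element(slab_up_vol, arr, 0, target, MarchConfig(max_length_mm=140.0))
        assert p.status is RayStatus.OK
        assert p.miss_distance <= 1e-9
        assert p.d_b == pytest.approx(np.linalg.norm(target - p.s2), abs=1e-9)
        assert p.theta_I_ws == pytest.approx(0.0, abs=1e-6)

    def test_steep_slab_exceeds_critical_angle(self):
        spec = PhantomSpec.slab(
            interface_z=40.0, thickness_mm=6.0, tilt_deg=40.0, spacing_mm=0.5,
            extent=((-20.0, 20.0), (-20.0, 20.0), (25.0, 52.0)),
        )
        vol = voxelize(spec)
        arr = TransducerArray(elements=[[0.0, 0.0, 120.0]])
        p = trace_element(vol, arr, 0, np.zeros(3), MarchConfig(max_length_mm=150.0))
        assert p.status is RayStatus.EXCEEDED_CRITICAL_ANGLE

    def test_axis_rays_on_shell_have_exact_normal_incidence(self, shell_cc_vol):
        dirs = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float
        )
        arr = TransducerArray(elements=120.0 * dirs)
        for i in range(6):
            p = trace_element(shell_cc_vol, arr, i, np.zeros(3), MarchConfig(max_length_mm=200.0))
            assert p.status is RayStatus.OK
            assert p.theta_I_ws == pytest.approx(0.0, abs=1e-6)
            assert np.allclose(p.h_b, p.h_w, atol=1e-9)
            assert p.miss_distance <= 0.2

    def test_snell_invariant_rechecked_from_stored_angles(self, shell_cc_vol):
        arr = TransducerArray(elements=120.0 * _fib_dirs(24))
        paths = trace_all(shell_cc_vol, arr, np.zeros(3), MarchConfig(max_length_mm=200.0), SpeedMap())
        ok = [p for p in paths if p.status is RayStatus.OK]
        assert len(ok) >= 20
        for p in ok:
            if p.theta_I_ws > 1e-12:
                assert np.sin(p.theta_I_ws) / np.sin(p.theta_T_ws) == pytest.approx(C_W / C_S, abs=1e-9)
            if p.theta_I_sb > 1e-12:
                assert np.sin(p.theta_I_sb) / np.sin(p.theta_T_sb) == pytest.approx(C_S / C_W, abs=1e-9)
            assert p.d_w == pytest.approx(np.linalg.norm(p.s1 - p.s0), abs=1e-9)
            assert p.d_s == pytest.approx(np.linalg.norm(p.s2 - p.s1), abs=1e-9)

    def test_no_skull_hit_keeps_water_path(self):
        vol = CTVolume(np.zeros((40, 40, 40)), spacing=(1.0, 1.0, 1.0))
        arr = TransducerArray(elements=[[-30.0, 20.0, 20.0]])
        target = np.array([60.0, 20.0, 20.0])
        p = trace_element(vol, arr, 0, target, MarchConfig(max_length_mm=150.0))
        assert p.status is RayStatus.NO_SKULL_HIT
        assert p.d_w == pytest.approx(90.0)
        assert p.d_s == 0.0


def _fib_dirs(n):
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(1.0 - z * z)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
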