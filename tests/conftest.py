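"""Shared phantom fixtures (session-scoped: voxelization is the slow part)."""

import numpy as np
import pytest

from skullray import PhantomSpec, voxelize


@pytest.fixture(scope="session")
def slab_up_spec():
    """Flat bone slab occupying 80 <= z < 86 mm, for rays travelling +z."""
    return PhantomSpec.slab(
        interface_z=80.0,
        thickness_mm=6.0,
        facing="up",
        spacing_mm=0.5,
        extent=((-15.0, 15.0), (-15.0, 15.0), (70.0, 95.0)),
    )


@pytest.fixture(scope="session")
def slab_up_vol(slab_up_spec):
    return voxelize(slab_up_spec)


@pytest.fixture(scope="session")
def shell_cc_spec():
    """Two 2 mm cortical tables (radii 50-52 and 55-57) around a 3 mm diploe."""
    return PhantomSpec.shell_with_cancellous(radii=(50.0, 52.0, 55.0, 57.0), spacing_mm=0.5)


@pytest.fixture(scope="session")
def shell_cc_vol(shell_cc_spec):
    return voxelize(shell_cc_spec)


@pytest.fixture(scope="session")
def fiducial_centers():
    rng = np.random.default_rng(11)
    # markers kept at z >= 0, away from the oversized test blob at z = -20
    def draw():
        return rng.uniform([-25.0, -25.0, 2.0], [25.0, 25.0, 25.0])

    pts = np.array([draw() for _ in range(8)])
    for _ in range(200):
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() > 10.0:
            break
        i = np.unravel_index(np.argmin(d), d.shape)[0]
        pts[i] = draw()
    return pts


@pytest.fixture(scope="session")
def fiducial_vol(fiducial_centers):
    spec = PhantomSpec.fiducial_frame(
        centers=fiducial_centers,
        diameter_mm=2.0,
        extra_spheres=[((0.0, 0.0, -20.0), 10.0, 3200.0)],
        spacing_mm=0.5,
        extent=((-32.0, 32.0), (-32.0, 32.0), (-32.0, 32.0)),
    )
    return voxelize(spec)
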