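import numpy as np
import pytest

from compax.geometry import (
    make_sphere_surface,
    promote_to_quadratic,
    sphere_projector,
    tetrahedralize,
)
from compax.material import Material

BEAD_RADIUS = 8.5
SPHERE_VOLUME = 4.0 / 3.0 * np.pi * BEAD_RADIUS**3  # 2572.44 um^3


@pytest.fixture(scope="session")
def material():
    return Material(E=1800.0, nu=0.443)


@pytest.fixture(scope="session")
def sphere_mesh_coarse():
    """Quadratic bead mesh, curved boundary, coarse (fast solves)."""
    surf = make_sphere_surface(BEAD_RADIUS, refinement=1)
    mesh = tetrahedralize(surf)
    return promote_to_quadratic(mesh, sphere_projector(np.zeros(3), BEAD_RADIUS))


@pytest.fixture(scope="session")
def sphere_mesh_straight():
    """Quadratic bead mesh with straight edges (midsides at chord midpoints)."""
    surf = make_sphere_surface(BEAD_RADIUS, refinement=1)
    return promote_to_quadratic(tetrahedralize(surf))


@pytest.fixture(scope="session")
def noiseless_stack():
    """Sharp, noise-free rendering of the nominal 17 um bead."""
    from compax.imaging import render_bead_stack

    surf = make_sphere_surface(BEAD_RADIUS, refinement=3)
    return render_bead_stack(surf, spacing_xy=0.1, spacing_z=1.0,
                             blur_sigma=0.0, noise_level=0.0)
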