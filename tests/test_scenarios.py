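"""Virtual load scenarios, forward simulations, and uncertainty analysis."""

import numpy as np
import pytest

from compax import fem
from compax.geometry import mesh_volume
from compax.scenarios import (
    build_bead_mesh,
    forward_solve,
    scenario_by_name,
    scenario_homogeneous,
    scenario_periodic,
    scenario_pressure_shear,
    scenario_quadratic,
    scenario_tractions,
    uncertainty_analysis,
)


def fibonacci_sphere(n=500):
    k = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * k
    z = 1 - 2 * k / n
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


class TestScenarioFields:
    def test_homogeneous_is_constant(self):
        sc = scenario_homogeneous(1000.0)
        np.testing.assert_allclose(sc.pressure(fibonacci_sphere()), 1000.0)

    def test_periodic_range_and_period_count(self):
        sc = scenario_periodic()
        # half-step offset keeps samples off the exact zeros of the sinusoid
        phi = np.linspace(0, 2 * np.pi, 4096, endpoint=False) + np.pi / 4096
        pts = np.column_stack([np.cos(phi), np.sin(phi), np.zeros_like(phi)])
        p = sc.pressure(pts)
        assert p.min() == pytest.approx(600.0, abs=0.5)
        assert p.max() == pytest.approx(1000.0, abs=0.5)
        # 8 full periods around the equator: 16 sign changes of p - mean,
        # including the wrap-around from the last sample back to the first
        s = np.sign(p - 800.0)
        crossings = int((s != np.roll(s, 1)).sum())
        assert crossings == 16

    def test_periodic_reduces_to_homogeneous(self):
        sc = scenario_periodic(p_min=700.0, p_max=700.0)
        np.testing.assert_allclose(sc.pressure(fibonacci_sphere()), 700.0)

    def test_periodic_requires_commensurate_wavelength(self):
        with pytest.raises(ValueError):
            scenario_periodic(wavelength=1.0)

    def test_quadratic_equator_and_poles(self):
        sc = scenario_quadratic()
        pts = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0], [0, 0, -1.0]])
        np.testing.assert_allclose(sc.pressure(pts), [1000.0, 1000.0, 600.0, 600.0])

    def test_quadratic_axisymmetric(self):
        sc = scenario_quadratic()
        phi = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        z = 0.6
        r = np.sqrt(1 - z**2)
        ring = np.column_stack([r * np.cos(phi), r * np.sin(phi), np.full_like(phi, z)])
        p = sc.pressure(ring)
        np.testing.assert_allclose(p, p[0], rtol=1e-12)

    def test_quadratic_equal_pressures_homogeneous(self):
        sc = scenario_quadratic(p_equator=800.0, p_pole=800.0)
        np.testing.assert_allclose(sc.pressure(fibonacci_sphere()), 800.0)

    def test_shear_tangential_and_magnitudes(self):
        sc = scenario_pressure_shear()
        pts = fibonacci_sphere()
        t = sc.traction(pts)
        np.testing.assert_allclose(np.einsum("ij,ij->i", t, pts), 0.0, atol=1e-10)
        np.testing.assert_allclose(np.linalg.norm(t, axis=1), 120.0, rtol=1e-9)
        np.testing.assert_allclose(sc.pressure(pts), 800.0)

    def test_shear_hemisphere_orientations(self):
        sc = scenario_pressure_shear()
        # on the x > 0 hemisphere the flow is north (+z) to south (-z)
        east = np.array([[1.0, 0.0, 0.0]]) * 0 + np.array([[np.sqrt(0.5), 0, np.sqrt(0.5)]])
        t = sc.traction(east)
        assert t[0, 2] < 0
        # on the x < 0 hemisphere it is east (+x) to west (-x)
        west = np.array([[-np.sqrt(0.5), 0.0, np.sqrt(0.5)]])
        t = sc.traction(west)
        assert t[0, 0] < 0

    def test_zero_shear_reduces_to_pressure_only(self):
        sc = scenario_pressure_shear(tau=0.0)
        t = sc.traction(fibonacci_sphere())
        np.testing.assert_allclose(t, 0.0)

    def test_unknown_scenario_lists_valid_names(self):
        with pytest.raises(ValueError, match="homogeneous"):
            scenario_by_name("twist")


class TestForwardSolve:
    def test_homogeneous_displacements_are_radial(self, material):
        mesh = build_bead_mesh(17.0, refinement=1)
        fld, _ = forward_solve(scenario_homogeneous(1000.0), mesh, material,
                               n_load_steps=2, tol=1e-12)
        # the pure-traction solve fixes the rigid-translation gauge at the
        # volume-weighted centroid; remove the best-fit translation before
        # decomposing into radial/tangential parts about the origin
        x = mesh.nodes
        u = fld.u
        xc, uc = x - x.mean(axis=0), u - u.mean(axis=0)
        c = float((xc * uc).sum() / (xc * xc).sum())
        u = u - (u.mean(axis=0) - c * x.mean(axis=0))
        r = np.linalg.norm(x, axis=1)
        inner = r > 1e-9
        xhat = x[inner] / r[inner, None]
        u_rad = np.einsum("ij,ij->i", u[inner], xhat)
        u_tan = np.linalg.norm(u[inner] - u_rad[:, None] * xhat, axis=1)
        assert u_tan.max() < 1e-6 * np.abs(u_rad).max()

    def test_mean_stress_identity_at_small_loads(self, material):
        # volume-mean stress equals (1/V) * surface integral of t (x) x
        from compax.stress import volumetric_mean

        from ._oracles import surface_load_moment

        mesh = build_bead_mesh(17.0, refinement=1)
        sc = scenario_quadratic(p_equator=50.0, p_pole=30.0)
        fld, sf = forward_solve(sc, mesh, material, n_load_steps=1)
        mean = volumetric_mean(sf)
        oracle = surface_load_moment(mesh, sc)
        scale = np.abs(oracle).max()
        assert np.abs(mean - oracle).max() < 0.02 * scale

    def test_tangential_loads_contribute_no_mean_pressure(self, material):
        # t . x = 0 on a sphere, so shear adds nothing to the mean stress trace
        mesh = build_bead_mesh(17.0, refinement=1)
        fld, sf = forward_solve(scenario_pressure_shear(p=50.0, tau=7.5), mesh,
                                material, n_load_steps=1)
        meanp = -np.einsum("pii,p->", sf.sigma, sf.volumes) / sf.volumes.sum() / 3
        assert meanp == pytest.approx(50.0, rel=0.02)


class TestUncertainty:
    def test_zero_spread_gives_zero_output_sd(self, material):
        out = uncertainty_analysis(
            scenario_homogeneous(200.0), diameter_sd=0.0, E_sd=0.0,
            n_samples=2, seed=1, refinement=0,
        )
        assert out.sd_pressure == pytest.approx(0.0, abs=1e-9 * abs(out.mean_pressure))

    def test_modulus_linearity_transfers_relative_spread(self):
        # stress scales linearly with E for a fixed observed shape, so the
        # relative spread of the reconstructed pressure equals that of E
        out = uncertainty_analysis(
            scenario_homogeneous(400.0), diameter_sd=0.0, E_sd=360.0,
            n_samples=5, seed=2, refinement=0,
        )
        rel_E = out.samples_E.std(ddof=1) / out.samples_E.mean()
        assert out.rel_sd_pressure == pytest.approx(rel_E, rel=0.02)
        # per-sample proportionality
        ratio = out.samples_pressure / out.samples_E
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-4)

    def test_deterministic_given_seed(self):
        kw = dict(diameter_sd=0.3, E_sd=200.0, n_samples=2, refinement=0)
        a = uncertainty_analysis(scenario_homogeneous(300.0), seed=7, **kw)
        b = uncertainty_analysis(scenario_homogeneous(300.0), seed=7, **kw)
        np.testing.assert_array_equal(a.samples_pressure, b.samples_pressure)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            uncertainty_analysis(scenario_homogeneous(), n_samples=1)
        with pytest.raises(ValueError):
            uncertainty_analysis(scenario_homogeneous(), E_sd=-1.0)
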