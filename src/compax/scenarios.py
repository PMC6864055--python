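"""Virtual load scenarios for validating the inverse reconstruction.

Four parametric surface-load patterns on the standard bead (17.0 µm
diameter, E = 1.8 kPa, nu = 0.443): homogeneous pressure, sinusoidally
periodic pressure around the equatorial angle, a quadratic pole-to-equator
pressure profile, and homogeneous pressure combined with hemispherical
tangential shear.  A forward reference simulation deforms the bead; the
inverse reconstruction then sees only the deformed shape, and both stress
summaries are compared.  A Monte-Carlo uncertainty analysis propagates
bead-diameter and Young's-modulus variability through the reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import fem
from .fem import TractionBC
from .geometry import (
    TetMesh,
    make_sphere_surface,
    mesh_volume,
    promote_to_quadratic,
    sphere_projector,
    tetrahedralize,
)
from .material import DEFAULT_MATERIAL, Material
from .pipeline import ReferenceSpec, run_compax
from .stress import (
    ComparisonRecord,
    StressSummary,
    compare_to_reference,
    summarize,
    surface_pressure_map,
)

__all__ = [
    "LoadScenario",
    "ValidationResult",
    "UncertaintySummary",
    "scenario_homogeneous",
    "scenario_periodic",
    "scenario_quadratic",
    "scenario_pressure_shear",
    "scenario_by_name",
    "SCENARIO_NAMES",
    "build_bead_mesh",
    "scenario_tractions",
    "forward_solve",
    "run_validation",
    "uncertainty_analysis",
]

_BEAD_DIAMETER = 17.0


@dataclass
class LoadScenario:
    """Surface pressure and tangential traction fields on the unit sphere.

    ``pressure(xhat)`` and ``traction(xhat)`` take unit direction vectors
    (points on the reference sphere scaled to unit radius) and return Pa
    values; tractions are tangential.
    """

    name: str
    pressure: Callable[[np.ndarray], np.ndarray]
    traction: Callable[[np.ndarray], np.ndarray] | None = None
    params: dict = field(default_factory=dict)


def scenario_homogeneous(p: float = 1000.0) -> LoadScenario:
    """Uniform surface pressure; the resulting displacements are radial."""
    return LoadScenario(
        name="homogeneous",
        pressure=lambda xhat: np.full(np.atleast_2d(xhat).shape[0], float(p)),
        params={"p": p},
    )


def scenario_periodic(
    p_min: float = 600.0, p_max: float = 1000.0, wavelength: float = np.pi / 4
) -> LoadScenario:
    """Pressure varying sinusoidally with the equatorial angle phi.

    ``p(phi) = (p_max + p_min)/2 + (p_max - p_min)/2 sin(2 pi phi /
    wavelength)``; the wavelength must divide 2 pi or the field would be
    discontinuous at phi = 0.
    """
    if p_max < p_min:
        raise ValueError("p_max must be >= p_min")
    n_per = 2.0 * np.pi / wavelength
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError("wavelength must divide 2*pi (periodic continuity)")

    mean, amp = 0.5 * (p_max + p_min), 0.5 * (p_max - p_min)

    def p(xhat: np.ndarray) -> np.ndarray:
        xhat = np.atleast_2d(xhat)
        phi = np.arctan2(xhat[:, 1], xhat[:, 0])
        return mean + amp * np.sin(2.0 * np.pi * phi / wavelength)

    return LoadScenario(
        name="periodic", pressure=p,
        params={"p_min": p_min, "p_max": p_max, "wavelength": wavelength},
    )


def scenario_quadratic(
    p_equator: float = 1000.0, p_pole: float = 600.0, axis=(0.0, 0.0, 1.0)
) -> LoadScenario:
    """Quadratic pressure along a rotation axis: max at the equator.

    With ``s = xhat . axis``: ``p(s) = p_equator - (p_equator - p_pole) s**2``.
    """
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)

    def p(xhat: np.ndarray) -> np.ndarray:
        s = np.atleast_2d(xhat) @ a
        return p_equator - (p_equator - p_pole) * s**2

    return LoadScenario(
        name="quadratic", pressure=p,
        params={"p_equator": p_equator, "p_pole": p_pole, "axis": tuple(a)},
    )


def _meridional_away_from(pole: np.ndarray, xhat: np.ndarray) -> np.ndarray:
    """Unit tangent pointing from the +pole toward the -pole, per point."""
    s = xhat @ pole
    t = s[:, None] * xhat - pole[None, :]
    nrm = np.linalg.norm(t, axis=1, keepdims=True)
    nrm[nrm < 1e-12] = 1.0  # exactly at a pole the direction is undefined
    return t / nrm


def scenario_pressure_shear(p: float = 800.0, tau: float = 120.0) -> LoadScenario:
    """Homogeneous pressure plus hemispherical tangential shear loads.

    On the hemisphere ``x > 0`` the shear (magnitude ``tau``) points along
    meridians from the north (+z) to the south (-z) pole; on ``x < 0`` it
    points from the east (+x) to the west (-x) pole.  Both fields are
    exactly tangential to the sphere.
    """
    ez = np.array([0.0, 0.0, 1.0])
    ex = np.array([1.0, 0.0, 0.0])

    def t(xhat: np.ndarray) -> np.ndarray:
        xhat = np.atleast_2d(xhat)
        north_south = _meridional_away_from(ez, xhat)
        east_west = _meridional_away_from(ex, xhat)
        east = (xhat[:, 0] > 0)[:, None]
        return tau * np.where(east, north_south, east_west)

    return LoadScenario(
        name="pressure_shear",
        pressure=lambda xhat: np.full(np.atleast_2d(xhat).shape[0], float(p)),
        traction=t,
        params={"p": p, "tau": tau},
    )


SCENARIO_NAMES = ("homogeneous", "periodic", "quadratic", "pressure_shear")


def scenario_by_name(name: str, **kwargs) -> LoadScenario:
    factories = {
        "homogeneous": scenario_homogeneous,
        "periodic": scenario_periodic,
        "quadratic": scenario_quadratic,
        "pressure_shear": scenario_pressure_shear,
    }
    if name not in factories:
        raise ValueError(f"unknown scenario {name!r}; valid: {sorted(factories)}")
    return factories[name](**kwargs)


# ---------------------------------------------------------------------------
# forward reference simulation and round trip
# ---------------------------------------------------------------------------


def build_bead_mesh(
    diameter: float = _BEAD_DIAMETER,
    refinement: int = 2,
    max_tet_volume: float | None = None,
) -> TetMesh:
    """Quadratic sphere mesh with boundary midside nodes on the sphere."""
    R = diameter / 2.0
    surf = make_sphere_surface(R, refinement)
    mesh = tetrahedralize(surf, max_tet_volume)
    return promote_to_quadratic(mesh, sphere_projector(np.zeros(3), R))


def scenario_tractions(scenario: LoadScenario, mesh: TetMesh) -> list[TractionBC]:
    """Scenario fields as traction BCs, sampled at face quadrature points."""
    faces = mesh.boundary_faces()

    def _norm(pts):
        return pts / np.linalg.norm(pts, axis=1, keepdims=True)

    out = [
        TractionBC(
            faces=faces, kind="pressure",
            pressure_fn=lambda pts: scenario.pressure(_norm(pts)),
        )
    ]
    if scenario.traction is not None:
        out.append(
            TractionBC(
                faces=faces, kind="shear",
                traction_fn=lambda pts: scenario.traction(_norm(pts)),
            )
        )
    return out


def forward_solve(
    scenario: LoadScenario,
    mesh: TetMesh,
    material: Material = DEFAULT_MATERIAL,
    n_load_steps: int = 5,
    tol: float = 1e-8,
):
    """Reference simulation: returns (displacement, stress field)."""
    tractions = scenario_tractions(scenario, mesh)
    fld = fem.solve_static(mesh, material, tractions=tractions,
                           n_load_steps=n_load_steps, tol=tol)
    return fld, fem.cauchy_stress(mesh, fld, material)


@dataclass
class ValidationResult:
    """Forward reference vs inverse reconstruction on one scenario."""

    scenario: LoadScenario
    reference_summary: StressSummary
    compax_summary: StressSummary
    comparison: ComparisonRecord
    deformed_mesh: TetMesh
    local_pressure_reference: np.ndarray
    local_pressure_compax: np.ndarray
    forward_mesh: TetMesh | None = None
    reference_stress: object = None
    compax_mesh: TetMesh | None = None
    compax_stress: object = None

    @property
    def local_pressure_discrepancy(self) -> float:
        """Maximum absolute local surface-pressure difference, Pa."""
        return float(
            np.abs(self.local_pressure_compax - self.local_pressure_reference).max()
        )

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario.name,
            "params": self.scenario.params,
            "reference": self.reference_summary.to_dict(),
            "compax": self.compax_summary.to_dict(),
            "delta_principal_Pa": self.comparison.delta_principal.tolist(),
            "delta_pressure_Pa": self.comparison.delta_pressure,
            "rel_delta_pressure": self.comparison.rel_delta_pressure,
            "principal_angles_deg": self.comparison.principal_angles_deg.tolist(),
            "local_pressure_discrepancy_Pa": self.local_pressure_discrepancy,
        }


def run_validation(
    scenario: LoadScenario,
    refinement: int = 2,
    material: Material = DEFAULT_MATERIAL,
    diameter: float = _BEAD_DIAMETER,
    n_load_steps: int = 5,
    tol: float = 1e-8,
) -> ValidationResult:
    """Forward simulate, reconstruct from the deformed shape, and compare.

    The reconstruction runs on the matched (forward-deformed) mesh, which
    isolates the method error of the radial-vector construction from
    imaging/segmentation error.
    """
    mesh = build_bead_mesh(diameter, refinement)
    V_r = mesh_volume(mesh)
    fld, ref_stress = forward_solve(scenario, mesh, material, n_load_steps, tol)
    ref_summary = summarize(ref_stress, V_r)

    deformed = mesh.with_nodes(mesh.nodes + fld.u)
    result = run_compax(deformed, material, ReferenceSpec(diameter=diameter),
                        n_load_steps=max(n_load_steps, 3), tol=tol)

    comparison = compare_to_reference(result.summary, ref_summary)
    return ValidationResult(
        scenario=scenario,
        reference_summary=ref_summary,
        compax_summary=result.summary,
        comparison=comparison,
        deformed_mesh=deformed,
        local_pressure_reference=surface_pressure_map(mesh, ref_stress),
        local_pressure_compax=surface_pressure_map(result.reference_mesh, result.stress),
        forward_mesh=mesh,
        reference_stress=ref_stress,
        compax_mesh=result.reference_mesh,
        compax_stress=result.stress,
    )


# ---------------------------------------------------------------------------
# uncertainty propagation
# ---------------------------------------------------------------------------


@dataclass
class UncertaintySummary:
    """Monte-Carlo spread of the reconstructed volumetric mean pressure."""

    samples_diameter: np.ndarray
    samples_E: np.ndarray
    samples_pressure: np.ndarray
    mean_pressure: float
    sd_pressure: float
    rel_sd_pressure: float


def _truncated_normal(rng, mean, sd, n, nsig=3.0):
    if sd == 0:
        return np.full(n, float(mean))
    out = np.empty(n)
    got = 0
    while got < n:
        draw = rng.normal(mean, sd, size=2 * (n - got))
        ok = draw[(np.abs(draw - mean) <= nsig * sd) & (draw > 0)]
        take = min(ok.size, n - got)
        out[got : got + take] = ok[:take]
        got += take
    return out


def uncertainty_analysis(
    scenario: LoadScenario,
    diameter_mean: float = 17.0,
    diameter_sd: float = 0.5,
    E_mean: float = 1800.0,
    E_sd: float = 700.0,
    nu: float = 0.443,
    n_samples: int = 16,
    seed: int = 0,
    refinement: int = 1,
) -> UncertaintySummary:
    """Propagate diameter and modulus uncertainty through the reconstruction.

    The scenario is forward-solved once with the nominal bead; the
    observed deformed shape is then reconstructed ``n_samples`` times with
    diameter and Young's modulus drawn from normal distributions truncated
    at ±3 SD (and at zero).  Reported is the spread of the volumetric mean
    pressure.  Deterministic for fixed ``seed``.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if diameter_sd < 0 or E_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    Ds = _truncated_normal(rng, diameter_mean, diameter_sd, n_samples)
    Es = _truncated_normal(rng, E_mean, E_sd, n_samples)

    nominal = Material(E=E_mean, nu=nu)
    mesh = build_bead_mesh(diameter_mean, refinement)
    fld, _ = forward_solve(scenario, mesh, nominal)
    deformed = mesh.with_nodes(mesh.nodes + fld.u)

    pressures = np.empty(n_samples)
    for i in range(n_samples):
        res = run_compax(deformed, Material(E=Es[i], nu=nu),
                         ReferenceSpec(diameter=Ds[i]))
        pressures[i] = res.summary.mean_pressure
    mean = float(pressures.mean())
    sd = float(pressures.std(ddof=1))
    return UncertaintySummary(
        samples_diameter=Ds,
        samples_E=Es,
        samples_pressure=pressures,
        mean_pressure=mean,
        sd_pressure=sd,
        rel_sd_pressure=sd / abs(mean) if mean != 0 else np.inf,
    )
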