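"""Scalar and tensor summaries of Cauchy stress fields.

The reported quantities follow the bead-sensor conventions: pressure is
the negative mean normal stress, ``sigma_pres = -tr(sigma)/3`` (positive =
compressive); the bead-level stress is the volume-weighted mean of the
integration-point Cauchy tensors; principal stresses are its eigenvalues
sorted descending.  Normal-stress-vs-angle profiles sample
``n(phi) . sigma . n(phi)`` for in-plane directions ``n(phi) = (cos phi,
sin phi, 0)`` and can be amplified about their per-time-point mean (the
mean itself is unchanged) and normalized by the global maximum absolute
value for visualization of stress-direction dynamics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .fem import StressField
from .geometry import TetMesh, _TET_FACES

__all__ = [
    "StressSummary",
    "NormalStressProfile",
    "ComparisonRecord",
    "pressure",
    "volumetric_mean",
    "principal",
    "summarize",
    "normal_stress_profile",
    "amplify_normalize",
    "compare_to_reference",
    "surface_pressure_map",
]


def pressure(sigma: np.ndarray, sym_tol: float = 1e-8) -> float:
    """Pressure ``-tr(sigma)/3`` of a symmetric stress tensor, Pa.

    Positive values indicate compressive isotropic stress.
    """
    sigma = np.asarray(sigma, float)
    if sigma.shape != (3, 3):
        raise ValueError("sigma must be 3x3")
    scale = max(float(np.abs(sigma).max()), 1e-300)
    if np.abs(sigma - sigma.T).max() > sym_tol * scale:
        raise ValueError("stress tensor is not symmetric within tolerance")
    return -float(np.trace(sigma)) / 3.0


def volumetric_mean(fld: StressField) -> np.ndarray:
    """Volume-weighted mean Cauchy tensor over all integration points."""
    if fld.sigma.shape[0] == 0:
        raise ValueError("empty stress field")
    vtot = float(fld.volumes.sum())
    if vtot <= 0:
        raise ValueError("total volume must be positive")
    mean = np.einsum("p,pij->ij", fld.volumes, fld.sigma) / vtot
    return 0.5 * (mean + mean.T)


def principal(sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal stresses (sorted descending) and orthonormal directions.

    Directions are returned as columns of a 3x3 matrix; each eigenvector's
    sign is fixed so its first nonzero component is positive.
    """
    sigma = np.asarray(sigma, float)
    vals, vecs = np.linalg.eigh(0.5 * (sigma + sigma.T))
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    for i in range(3):
        v = vecs[:, i]
        nz = np.nonzero(np.abs(v) > 1e-12)[0]
        if nz.size and v[nz[0]] < 0:
            vecs[:, i] = -v
    return vals, vecs


@dataclass
class StressSummary:
    """Bead-level stress state: mean tensor, principal system, pressure."""

    mean_tensor: np.ndarray
    principal_values: np.ndarray
    principal_directions: np.ndarray  # columns match principal_values
    mean_pressure: float
    V_c: float
    V_r: float

    def to_dict(self) -> dict:
        return {
            "mean_tensor_Pa": self.mean_tensor.tolist(),
            "principal_values_Pa": self.principal_values.tolist(),
            "principal_directions": self.principal_directions.tolist(),
            "mean_pressure_Pa": self.mean_pressure,
            "current_volume_um3": self.V_c,
            "reference_volume_um3": self.V_r,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def summarize(fld: StressField, V_r: float) -> StressSummary:
    """Volumetric summary of a stress field against a reference volume."""
    mean = volumetric_mean(fld)
    vals, vecs = principal(mean)
    return StressSummary(
        mean_tensor=mean,
        principal_values=vals,
        principal_directions=vecs,
        mean_pressure=pressure(mean),
        V_c=float(fld.volumes.sum()),
        V_r=float(V_r),
    )


@dataclass
class NormalStressProfile:
    """In-plane normal stress vs direction angle phi (radians in [0, 2pi))."""

    angles: np.ndarray
    values: np.ndarray
    amplification: float = 1.0
    normalized: bool = False

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def max_amplitude_angle(self) -> float:
        """Direction of the largest deviation from the profile mean."""
        return float(self.angles[np.argmax(np.abs(self.values - self.values.mean()))])


def normal_stress_profile(sigma_mean: np.ndarray, n_angles: int = 360) -> NormalStressProfile:
    """Normal stress ``n . sigma . n`` for in-plane directions ``n(phi)``."""
    if n_angles < 4:
        raise ValueError("need at least 4 angles")
    sigma_mean = np.asarray(sigma_mean, float)
    phi = 2.0 * np.pi * np.arange(n_angles) / n_angles
    n = np.stack([np.cos(phi), np.sin(phi), np.zeros_like(phi)], axis=1)
    vals = np.einsum("ai,ij,aj->a", n, sigma_mean, n)
    return NormalStressProfile(angles=phi, values=vals)


def amplify_normalize(
    profiles: list[NormalStressProfile], factor: float = 5.0
) -> list[NormalStressProfile]:
    """Amplify fluctuations about each profile's mean, then normalize globally.

    Per time point ``t``: ``v'(phi) = m_t + factor (v(phi) - m_t)`` with
    ``m_t`` the mean over phi (unchanged by the amplification); the whole
    series is then divided by the maximum of ``|v'|`` over all time points
    and angles, so the largest absolute value is exactly 1.
    """
    if not profiles:
        raise ValueError("empty profile series")
    amped = []
    for p in profiles:
        m = p.values.mean()
        amped.append(m + factor * (p.values - m))
    gmax = max(float(np.abs(a).max()) for a in amped)
    if gmax == 0.0:
        raise ValueError("all-zero profile series: normalization undefined")
    return [
        NormalStressProfile(
            angles=p.angles.copy(),
            values=a / gmax,
            amplification=factor,
            normalized=True,
        )
        for p, a in zip(profiles, amped)
    ]


@dataclass
class ComparisonRecord:
    """Reconstruction-vs-reference comparison of two stress summaries.

    ``delta_principal`` are the per-principal-value differences
    (reconstructed minus reference, Pa); ``rel_delta_pressure`` is the
    relative mean-pressure difference (None when the reference pressure
    is zero); ``principal_angles_deg`` are the angles between matched
    principal directions, evaluated subspace-wise when eigenvalues are
    degenerate within ``degeneracy_tol`` of the spectral scale.
    """

    delta_principal: np.ndarray
    delta_pressure: float
    rel_delta_pressure: float | None
    principal_angles_deg: np.ndarray
    degenerate_clusters: list = field(default_factory=list)


def _eig_clusters(vals: np.ndarray, tol_abs: float) -> list[list[int]]:
    clusters = [[0]]
    for i in (1, 2):
        if abs(vals[i] - vals[clusters[-1][-1]]) <= tol_abs:
            clusters[-1].append(i)
        else:
            clusters.append([i])
    return clusters


def compare_to_reference(
    cmx: StressSummary, ref: StressSummary, degeneracy_tol: float = 0.05
) -> ComparisonRecord:
    """Differences in principal values, mean pressure, and directions.

    Eigenvectors belonging to (nearly) repeated eigenvalues are not
    individually well defined, so direction angles are computed between
    each reference eigenvector and the span of the reconstructed
    eigenvectors of the matching eigenvalue cluster.
    """
    dvals = cmx.principal_values - ref.principal_values
    dp = cmx.mean_pressure - ref.mean_pressure
    rel = dp / ref.mean_pressure if ref.mean_pressure != 0 else None

    scale = max(
        float(np.abs(ref.principal_values).max()),
        float(np.abs(cmx.principal_values).max()),
        1e-300,
    )
    clusters = _eig_clusters(ref.principal_values, degeneracy_tol * scale)
    angles = np.empty(3)
    for cl in clusters:
        Vc = cmx.principal_directions[:, cl]  # subspace of matched cluster
        for i in cl:
            v = ref.principal_directions[:, i]
            proj = Vc @ (Vc.T @ v)
            c = np.clip(np.linalg.norm(proj), -1.0, 1.0)
            angles[i] = np.degrees(np.arccos(c))
    return ComparisonRecord(
        delta_principal=dvals,
        delta_pressure=dp,
        rel_delta_pressure=rel,
        principal_angles_deg=angles,
        degenerate_clusters=clusters,
    )


def surface_pressure_map(mesh: TetMesh, fld: StressField) -> np.ndarray:
    """Per-boundary-face pressure: volume-weighted over the owning element.

    Local surface-pressure contour analogue; faces are ordered as in
    ``mesh.boundary_faces()``, so maps from reconstructions on matched
    meshes are directly comparable.
    """
    nel = mesh.n_elements
    pres = -np.einsum("pii->p", fld.sigma) / 3.0
    num = np.bincount(fld.element_ids, weights=pres * fld.volumes, minlength=nel)
    den = np.bincount(fld.element_ids, weights=fld.volumes, minlength=nel)
    el_pressure = num / den

    corners = mesh.elements[:, :4]
    all_faces = corners[:, _TET_FACES].reshape(-1, 3)
    owner = np.repeat(np.arange(nel), 4)
    keys = {}
    for f, e in zip(np.sort(all_faces, axis=1).tolist(), owner):
        t = tuple(f)
        if t in keys:
            keys[t] = -1  # interior
        else:
            keys[t] = int(e)
    bfaces = mesh.boundary_faces()
    out = np.empty(bfaces.shape[0])
    for i, f in enumerate(np.sort(bfaces[:, :3], axis=1).tolist()):
        out[i] = el_pressure[keys[tuple(f)]]
    return out
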