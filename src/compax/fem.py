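"""Geometrically nonlinear finite elements for a compressible Neo-Hookean solid.

Total-Lagrangian displacement formulation on 4-node (linear) or 10-node
(quadratic) tetrahedra.  The strain-energy density is

    W(F) = mu/2 (I1 - 3) - mu ln J + lambda/2 (ln J)^2,

which linearizes to isotropic elasticity with Young's modulus ``E`` and
Poisson ratio ``nu``.  Surface pressures are follower loads (they act
along the current surface normal on the current area); tangential shear
tractions are dead loads (fixed direction, reference area).  Newton's
method with full consistent tangent (including the follower-load
stiffness) and adaptive load stepping solves the equilibrium equations;
pure-traction problems are regularized by Lagrange-multiplier constraints
on the volume-weighted net translation and linearized rotation.

Units: coordinates in µm, moduli and stresses in Pa (forces are then in
Pa·µm² = pN); the mix is consistent and requires no internal scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .geometry import TetMesh, tet10_shape_gradients, tri6_shape
from .material import Material

__all__ = [
    "DirichletBC",
    "TractionBC",
    "DisplacementField",
    "StressField",
    "SolverError",
    "ElementInversionError",
    "solve_static",
    "cauchy_stress",
    "hydrostatic_compression",
    "hydrostatic_stress",
]


class SolverError(RuntimeError):
    """Newton iteration failed to converge."""

    def __init__(self, msg: str, last_converged_fraction: float = 0.0):
        super().__init__(msg)
        self.last_converged_fraction = last_converged_fraction


class ElementInversionError(SolverError):
    """An element Jacobian became non-positive."""

    def __init__(self, element_id: int):
        super().__init__(f"element {element_id} inverted (J <= 0)")
        self.element_id = element_id


@dataclass
class DirichletBC:
    """Prescribed displacements (µm) at a set of node ids."""

    node_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.node_ids.ndim != 1 or np.unique(self.node_ids).size != self.node_ids.size:
            raise ValueError("node_ids must be unique")
        if self.values.shape != (self.node_ids.size, 3):
            raise ValueError("values must be (n_nodes, 3)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("prescribed displacements must be finite")


@dataclass
class TractionBC:
    """Surface load on a set of boundary faces.

    ``kind='pressure'``: per-face normal pressure in Pa, positive =
    compressive, applied as a follower load.  ``kind='shear'``: per-face
    traction vector in Pa with fixed (dead) direction, integrated over
    the reference area.
    """

    faces: np.ndarray  # (k, 3) or (k, 6) node connectivity, outward wound
    kind: str = "pressure"
    pressure: np.ndarray | None = None  # (k,)
    traction: np.ndarray | None = None  # (k, 3)
    #: optional fields evaluated at the face quadrature points (reference
    #: coordinates -> Pa); they override the per-face constants and avoid
    #: aliasing of rapidly varying loads on coarse meshes
    pressure_fn: object = None
    traction_fn: object = None

    def __post_init__(self) -> None:
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.kind not in ("pressure", "shear"):
            raise ValueError("kind must be 'pressure' or 'shear'")
        if self.kind == "pressure" and self.pressure_fn is None:
            self.pressure = np.broadcast_to(
                np.asarray(self.pressure, float), (self.faces.shape[0],)
            ).copy()
            if not np.all(np.isfinite(self.pressure)):
                raise ValueError("pressure must be finite")
        elif self.kind == "shear" and self.traction_fn is None:
            self.traction = np.broadcast_to(
                np.asarray(self.traction, float), (self.faces.shape[0], 3)
            ).copy()
            if not np.all(np.isfinite(self.traction)):
                raise ValueError("traction must be finite")


@dataclass
class DisplacementField:
    """Per-node displacements (µm) with Newton convergence metadata."""

    u: np.ndarray
    converged: bool = True
    newton_iterations: list = field(default_factory=list)


@dataclass
class StressField:
    """Cauchy stress state at the integration points.

    ``sigma``: (npts, 3, 3) Cauchy tensors in Pa; ``volumes``: current
    (deformed) integration-point volumes in µm³; ``J``: local volume
    ratio; ``element_ids``: owning element per point.
    """

    sigma: np.ndarray
    volumes: np.ndarray
    J: np.ndarray
    element_ids: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.volumes <= 0) or np.any(self.J <= 0):
            raise ValueError("integration-point volumes and J must be positive")


# ---------------------------------------------------------------------------
# quadrature and kinematics
# ---------------------------------------------------------------------------

_A4 = 0.5854101966249685
_B4 = 0.1381966011250105
#: degree-2 rule with positive weights: used for stress recovery so that
#: every integration point carries a positive volume share
_TET4PT = np.array(
    [
        [_B4, _B4, _B4],
        [_A4, _B4, _B4],
        [_B4, _A4, _B4],
        [_B4, _B4, _A4],
    ]
)
_TET4WT = np.full(4, 0.25 / 6.0)


def _keast11() -> tuple[np.ndarray, np.ndarray]:
    # degree-4 11-point rule (one negative centroid weight); used for
    # assembly, where accurate integration on curved isoparametric
    # elements matters more than weight positivity
    import itertools

    a, b = 0.7857142857142857, 0.07142857142857141
    c = 0.39940357616679916
    d = 0.5 - c
    pts = [[0.25, 0.25, 0.25, 0.25]]
    wts = [-0.013155555555555555]
    for i in range(4):
        q = [b] * 4
        q[i] = a
        pts.append(q)
        wts.append(0.007622222222222222)
    for i, j in itertools.combinations(range(4), 2):
        q = [d] * 4
        q[i] = c
        q[j] = c
        pts.append(q)
        wts.append(0.024888888888888887)
    return np.array(pts)[:, 1:], np.array(wts)


_TET11PT, _TET11WT = _keast11()

_EPS = np.zeros((3, 3, 3))
for _i, _j, _k in [(0, 1, 2), (1, 2, 0), (2, 0, 1)]:
    _EPS[_i, _j, _k] = 1.0
    _EPS[_i, _k, _j] = -1.0


def _tet4_gradients() -> tuple[np.ndarray, np.ndarray]:
    # linear tet: constant gradients, single centroid point
    g = np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])[None]
    return g, np.array([1.0 / 6.0])


class _ElementData:
    """Reference-configuration element quantities reused across iterations.

    ``purpose='assembly'`` uses a degree-4 rule on quadratic elements
    (accurate on curved boundary elements); ``purpose='stress'`` uses the
    positive-weight degree-2 rule so integration-point volumes are
    meaningful.
    """

    def __init__(self, mesh: TetMesh, purpose: str = "assembly"):
        self.mesh = mesh
        if mesh.order == 2:
            if purpose == "assembly":
                pts, wts = _TET11PT, _TET11WT
            else:
                pts, wts = _TET4PT, _TET4WT
            g = tet10_shape_gradients(pts)  # (q, 10, 3)
        else:
            g, wts = _tet4_gradients()
        x = mesh.nodes[mesh.elements]  # (nel, nn, 3)
        Jref = np.einsum("qam,eai->eqmi", g, x)  # dX/dxi, (nel, q, 3, 3)
        detJ = np.linalg.det(Jref)
        if np.any(detJ <= 0):
            bad = int(np.nonzero((detJ <= 0).any(axis=1))[0][0])
            raise ElementInversionError(bad)
        Jinv = np.linalg.inv(Jref)
        # Jref[m, i] = dX_i/dxi_m, so dN_a/dX_i = g[a, m] (Jref^-T)[m, i]
        # with (Jref^-T)[m, i] = Jinv[i, m]
        self.dNdX = np.einsum("qam,eqim->eqai", g, Jinv)
        self.wdet = wts[None, :] * detJ  # (nel, q)
        nn = mesh.elements.shape[1]
        dofs = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(-1, 3 * nn)
        self.edofs = dofs  # (nel, 3nn)
        self.rows = np.repeat(dofs, 3 * nn, axis=1).ravel()
        self.cols = np.tile(dofs, (1, 3 * nn)).ravel()
        self.ndof = 3 * mesh.n_nodes


def _deformation_gradients(data: _ElementData, u: np.ndarray) -> np.ndarray:
    ue = u[data.mesh.elements]  # (nel, nn, 3)
    F = np.einsum("eai,eqam->eqim", ue, data.dNdX)
    F += np.eye(3)[None, None]
    return F  # (nel, q, 3, 3)


def _check_J(J: np.ndarray) -> None:
    if np.any(J <= 0):
        bad = int(np.nonzero((J <= 0).any(axis=1))[0][0])
        raise ElementInversionError(bad)


def _internal_forces(data: _ElementData, u: np.ndarray, mat: Material,
                     want_tangent: bool) -> tuple[np.ndarray, np.ndarray | None, float]:
    """Assembled internal force, optional tangent COO values, and force scale."""
    mu, lam = mat.mu, mat.lam
    F = _deformation_gradients(data, u)
    J = np.linalg.det(F)
    _check_J(J)
    Finv = np.linalg.inv(F)
    FinvT = np.swapaxes(Finv, -1, -2)
    lnJ = np.log(J)
    # first Piola-Kirchhoff stress
    P = mu * F + (lam * lnJ - mu)[..., None, None] * FinvT

    w = data.wdet  # (nel, q)
    # fe[a, i] = sum_q w P_iJ dN_a/dX_J
    fe = np.einsum("eq,eqaJ,eqiJ->eai", w, data.dNdX, P)

    fint = np.zeros(data.ndof)
    np.add.at(fint, (3 * data.mesh.elements[:, :, None] + np.arange(3)).ravel(),
              fe.ravel())

    scale = float(np.sqrt((fe**2).sum() / max(fe.shape[0], 1)))

    if not want_tangent:
        return fint, None, scale

    # material tangent A_iJkL = mu d_ik d_JL + lam Finv_Ji Finv_Lk
    #                          - (lam lnJ - mu) Finv_Jk Finv_Li
    nel, nq = F.shape[:2]
    A = np.zeros((nel, nq, 3, 3, 3, 3))
    eye = np.eye(3)
    A += mu * np.einsum("ik,JL->iJkL", eye, eye)[None, None]
    A += lam * np.einsum("eqJi,eqLk->eqiJkL", Finv, Finv)
    A -= (lam * lnJ - mu)[..., None, None, None, None] * np.einsum(
        "eqJk,eqLi->eqiJkL", Finv, Finv
    )
    Ke = np.einsum("eq,eqaJ,eqiJkL,eqbL->eaibk", w, data.dNdX, A, data.dNdX,
                   optimize=True)
    nn = data.mesh.elements.shape[1]
    vals = Ke.reshape(nel, 3 * nn, 3 * nn).ravel()
    return fint, vals, scale


# ---------------------------------------------------------------------------
# surface loads
# ---------------------------------------------------------------------------

_TRI3PT = np.array([[1.0 / 3.0, 1.0 / 3.0]])
_TRI3WT = np.array([0.5])
# degree-4 6-point rule for quadratic (possibly curved) faces
from .geometry import _TRI6_PTS as _TRI6PT  # noqa: E402
from .geometry import _TRI6_WTS as _TRI6WT  # noqa: E402


def _face_shape(nfn: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if nfn == 3:
        pts, wts = _TRI3PT, _TRI3WT
        vals = np.stack([1 - pts[:, 0] - pts[:, 1], pts[:, 0], pts[:, 1]], axis=1)
        grads = np.broadcast_to(
            np.array([[-1.0, -1.0], [1, 0], [0, 1]])[None], (pts.shape[0], 3, 2)
        ).copy()
    else:
        pts, wts = _TRI6PT, _TRI6WT
        vals, grads = tri6_shape(pts)
    return vals, grads, wts


class _FollowerLoad:
    """Follower normal-pressure load on boundary faces, with exact tangent.

    The pressure is a material field: per quadrature point when the
    traction carries a ``pressure_fn``, else constant per face.
    """

    def __init__(self, bc: TractionBC, n_nodes: int, nodes: np.ndarray):
        self.faces = bc.faces
        self.vals, self.grads, self.wts = _face_shape(bc.faces.shape[1])
        if bc.pressure_fn is not None:
            xq0 = np.einsum("qa,kai->kqi", self.vals, nodes[bc.faces])
            self.p = np.asarray(
                bc.pressure_fn(xq0.reshape(-1, 3)), float
            ).reshape(xq0.shape[:2])  # (k, q)
        else:
            self.p = np.broadcast_to(
                bc.pressure[:, None], (bc.faces.shape[0], self.wts.size)
            )
        nfn = bc.faces.shape[1]
        dofs = (3 * bc.faces[:, :, None] + np.arange(3)).reshape(-1, 3 * nfn)
        self.fdofs = dofs
        self.rows = np.repeat(dofs, 3 * nfn, axis=1).ravel()
        self.cols = np.tile(dofs, (1, 3 * nfn)).ravel()
        self.ndof = 3 * n_nodes

    def force_and_tangent(self, nodes: np.ndarray, u: np.ndarray, factor: float,
                          want_tangent: bool):
        x = (nodes + u)[self.faces]  # (k, nfn, 3) current coords
        a1 = np.einsum("qam,kai->kqim", self.grads, x)  # (k, q, 3, 2)
        axi, aeta = a1[..., 0], a1[..., 1]
        nvec = np.cross(axi, aeta)  # (k, q, 3), outward, |n| = 2*area/ref
        p = factor * self.p  # (k, q)
        # f_a = -p sum_q w N_a nvec
        fe = -np.einsum("kq,q,qa,kqi->kai", p, self.wts, self.vals, nvec)
        f = np.zeros(self.ndof)
        np.add.at(f, (3 * self.faces[:, :, None] + np.arange(3)).ravel(), fe.ravel())
        if not want_tangent:
            return f, None
        # d f_a / d u_b = -p w N_a [ dNxi_b (du x aeta) + dNeta_b (axi x du) ]
        # (du x aeta)_i = eps_ijl du_j aeta_l  -> M1[i, j] = eps_ijl aeta_l
        # (axi x du)_i = eps_ijl axi_j du_l   -> M2[i, l] = eps_ijl axi_j
        M1 = np.einsum("ijl,kql->kqij", _EPS, aeta)
        M2 = np.einsum("ijl,kqj->kqil", _EPS, axi)
        Kf = -np.einsum("kq,q,qa,kqij,qb->kaibj", p, self.wts, self.vals, M1,
                        self.grads[:, :, 0], optimize=True)
        Kf -= np.einsum("kq,q,qa,kqij,qb->kaibj", p, self.wts, self.vals, M2,
                        self.grads[:, :, 1], optimize=True)
        nfn = self.faces.shape[1]
        return f, Kf.reshape(self.faces.shape[0], 3 * nfn, 3 * nfn).ravel()


def _dead_load_vector(bc: TractionBC, mesh: TetMesh) -> np.ndarray:
    """Reference-area integral of a fixed traction vector."""
    vals, grads, wts = _face_shape(bc.faces.shape[1])
    x = mesh.nodes[bc.faces]
    a1 = np.einsum("qam,kai->kqim", grads, x)
    nvec = np.cross(a1[..., 0], a1[..., 1])
    dA = np.linalg.norm(nvec, axis=-1)  # (k, q)
    if bc.traction_fn is not None:
        xq0 = np.einsum("qa,kai->kqi", vals, x)
        t = np.asarray(bc.traction_fn(xq0.reshape(-1, 3)), float).reshape(
            x.shape[0], wts.size, 3
        )
        fe = np.einsum("q,kq,qa,kqi->kai", wts, dA, vals, t)
    else:
        fe = np.einsum("q,kq,qa,ki->kai", wts, dA, vals, bc.traction)
    f = np.zeros(3 * mesh.n_nodes)
    np.add.at(f, (3 * bc.faces[:, :, None] + np.arange(3)).ravel(), fe.ravel())
    return f


def _rigid_body_constraints(mesh: TetMesh) -> sparse.csr_matrix:
    """Volume-weighted net-translation and net-rotation constraint rows."""
    w = np.zeros(mesh.n_nodes)
    v = np.abs(mesh.corner_volumes())
    np.add.at(w, mesh.elements[:, :4].ravel(), np.repeat(v / 4.0, 4))
    if mesh.order == 2:
        # midside nodes carry no corner lump; give them a small share
        mids = np.unique(mesh.elements[:, 4:])
        w[mids] = np.maximum(w[mids], v.mean() * 1e-3)
    w = w / w.sum()
    xbar = (w[:, None] * mesh.nodes).sum(axis=0)
    r = mesh.nodes - xbar
    n = mesh.n_nodes
    C = np.zeros((6, 3 * n))
    for d in range(3):
        C[d, d::3] = w
    # rotation: sum_i w_i (r_i x u_i)_a = sum_i w_i eps_abg r_ib u_ig = 0
    for a in range(3):
        for g in range(3):
            C[3 + a, g::3] = w * (r @ _EPS[a, :, g])
    return sparse.csr_matrix(C)


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------


def solve_static(
    mesh: TetMesh,
    material: Material,
    dirichlet: DirichletBC | None = None,
    tractions: list[TractionBC] | tuple = (),
    n_load_steps: int = 5,
    tol: float = 1e-8,
    max_iter: int = 30,
    max_halvings: int = 8,
) -> DisplacementField:
    """Static equilibrium under displacement and traction boundary conditions.

    Loads and prescribed displacements are ramped proportionally in
    ``n_load_steps`` increments (halved adaptively on Newton divergence
    or element inversion).  Without any Dirichlet data the six rigid-body
    modes are removed by Lagrange-multiplier constraints on the
    volume-weighted mean translation and linearized rotation.
    """
    data = _ElementData(mesh)
    ndof = data.ndof
    u = np.zeros((mesh.n_nodes, 3))

    fixed = np.zeros(ndof, dtype=bool)
    ud_full = np.zeros(ndof)
    if dirichlet is not None and dirichlet.node_ids.size:
        dd = (3 * dirichlet.node_ids[:, None] + np.arange(3)).ravel()
        fixed[dd] = True
        ud_full[dd] = dirichlet.values.ravel()
    free = ~fixed

    followers = [
        _FollowerLoad(t, mesh.n_nodes, mesh.nodes)
        for t in tractions
        if t.kind == "pressure"
    ]
    f_dead = np.zeros(ndof)
    for t in tractions:
        if t.kind == "shear":
            f_dead += _dead_load_vector(t, mesh)

    use_rb = not fixed.any()
    C = _rigid_body_constraints(mesh) if use_rb else None
    lam_rb = np.zeros(6)

    iters_per_step: list[int] = []
    lam_done = 0.0
    dlam = 1.0 / max(n_load_steps, 1)
    halvings = 0

    while lam_done < 1.0 - 1e-12:
        lam_t = min(1.0, lam_done + dlam)
        u_try = u.copy()
        uf = u_try.reshape(-1)
        uf[fixed] = lam_t * ud_full[fixed]
        ok, nit = _newton(
            data, material, u_try, free, followers, f_dead, lam_t, C, lam_rb,
            tol, max_iter,
        )
        if ok:
            u = u_try
            lam_done = lam_t
            iters_per_step.append(nit)
            halvings = 0
        else:
            dlam *= 0.5
            halvings += 1
            if halvings > max_halvings:
                raise SolverError(
                    f"Newton diverged; last converged load fraction {lam_done:.4f}"
                    " (try more load steps)",
                    last_converged_fraction=lam_done,
                )
    return DisplacementField(u=u, converged=True, newton_iterations=iters_per_step)


def _newton(data, material, u, free, followers, f_dead, factor, C, lam_rb,
            tol, max_iter) -> tuple[bool, int]:
    mesh = data.mesh
    uflat = u.reshape(-1)
    # absolute floor: a Newton update far below any resolvable displacement
    # means the residual sits at the round-off floor (e.g. zero-load states)
    L = float(np.linalg.norm(mesh.nodes.max(axis=0) - mesh.nodes.min(axis=0)))
    du_floor = 1e-13 * max(L, 1e-30)
    for it in range(max_iter):
        try:
            fint, kvals, fscale = _internal_forces(data, u, material, True)
        except ElementInversionError:
            return False, it
        fext = factor * f_dead
        K_rows = [data.rows]
        K_cols = [data.cols]
        K_vals = [kvals]
        for fl in followers:
            ff, kf = fl.force_and_tangent(mesh.nodes, u, factor, True)
            fext = fext + ff
            K_rows.append(fl.rows)
            K_cols.append(fl.cols)
            # external tangent enters with negative sign in K du = -R
            K_vals.append(-kf)
        R = fint - fext

        K = sparse.coo_matrix(
            (np.concatenate(K_vals), (np.concatenate(K_rows), np.concatenate(K_cols))),
            shape=(data.ndof, data.ndof),
        ).tocsr()

        ref = max(float(np.linalg.norm(fext[free])), fscale, 1e-30)
        if C is None:
            resnorm = float(np.linalg.norm(R[free]))
            if resnorm <= tol * ref:
                return True, it
            idx = np.nonzero(free)[0]
            Kff = K[idx][:, idx].tocsc()
            du = spsolve(Kff, -R[idx])
            if not np.all(np.isfinite(du)):
                return False, it
            uflat[idx] += du
            if np.abs(du).max() < du_floor:
                return True, it + 1
        else:
            # augmented saddle system with rigid-body constraint rows; the
            # multiplier force C^T lam balances the (tiny) quadrature
            # imbalance of nearly self-equilibrated surface loads and
            # belongs in the equilibrium residual
            scale = max(abs(K.diagonal()).mean(), 1.0)
            Caug = C * scale
            Rtot = R + Caug.T @ lam_rb
            resnorm = float(
                np.hypot(np.linalg.norm(Rtot), scale * np.linalg.norm(C @ uflat))
            )
            if resnorm <= tol * ref:
                return True, it
            A = sparse.bmat([[K, Caug.T], [Caug, None]], format="csc")
            rhs = np.concatenate([-Rtot, -(Caug @ uflat)])
            sol = spsolve(A, rhs)
            if not np.all(np.isfinite(sol)):
                return False, it
            uflat += sol[: data.ndof]
            lam_rb += sol[data.ndof :]
            if np.abs(sol[: data.ndof]).max() < du_floor:
                return True, it + 1
    return False, max_iter


# ---------------------------------------------------------------------------
# stress recovery and hydrostatic oracle
# ---------------------------------------------------------------------------


def cauchy_stress(mesh: TetMesh, fld: DisplacementField, material: Material) -> StressField:
    """Cauchy stress, current volume and J at every integration point."""
    data = _ElementData(mesh, purpose="stress")
    F = _deformation_gradients(data, fld.u)
    J = np.linalg.det(F)
    _check_J(J)
    B = np.einsum("eqik,eqjk->eqij", F, F)
    mu, lam = material.mu, material.lam
    sigma = (mu * (B - np.eye(3)[None, None]) +
             (lam * np.log(J))[..., None, None] * np.eye(3)[None, None])
    sigma /= J[..., None, None]
    nel, nq = J.shape
    vols = (data.wdet * J).reshape(-1)
    eids = np.repeat(np.arange(nel), nq)
    return StressField(
        sigma=sigma.reshape(-1, 3, 3), volumes=vols, J=J.reshape(-1), element_ids=eids
    )


def hydrostatic_stress(J: float, material: Material) -> float:
    """Radial Cauchy stress of the uniform dilatation ``F = J^(1/3) I``.

    For the Neo-Hookean energy used here the stress of a uniform
    dilatation is isotropic, ``sigma = s(J) I`` with
    ``s(J) = (mu (J^(2/3) - 1) + lambda ln J) / J``.
    """
    mu, lam = material.mu, material.lam
    return (mu * (J ** (2.0 / 3.0) - 1.0) + lam * np.log(J)) / J


def hydrostatic_compression(p: float, material: Material) -> float:
    """Volume ratio ``J`` of a bead under homogeneous surface pressure ``p``.

    Solves the scalar radial equilibrium ``s(J) + p = 0`` by bisection
    (``brentq``); ``p > 0`` compresses (``J < 1``), ``p < 0`` dilates.
    The tensile branch has a finite maximum sustainable traction; beyond
    it no equilibrium exists and a ``ValueError`` is raised.
    """
    from scipy.optimize import brentq

    if p == 0.0:
        return 1.0
    f = lambda J: hydrostatic_stress(J, material) + p
    if p > 0.0:
        lo = 1e-8
        return float(brentq(f, lo, 1.0, xtol=1e-15, rtol=8.9e-16))
    # tension: f(1) = p < 0 and s(J) rises to its maximum before softening;
    # take the first (stable-branch) root
    hi = 1.0 + 1e-3
    for _ in range(60):
        if f(hi) > 0.0:
            return float(brentq(f, 1.0, hi, xtol=1e-15, rtol=8.9e-16))
        hi *= 1.5
    raise ValueError(
        f"tension {-p} Pa exceeds the maximum sustainable hydrostatic traction"
    )
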