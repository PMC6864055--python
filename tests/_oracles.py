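"""Independent oracles used by the tests.

Self-contained quadratic-surface integration (own basis and quadrature
constants) for the small-strain mean-stress identity

    mean sigma = (1/V) * surface integral of t (x) x dA,

evaluated on the curved boundary of a quadratic tet mesh.
"""

import numpy as np

# 6-point degree-4 triangle rule (weights sum to 1/2)
_QA = 0.445948490915965
_QB = 0.091576213509771
_QPTS = np.array(
    [
        [_QA, _QA],
        [1 - 2 * _QA, _QA],
        [_QA, 1 - 2 * _QA],
        [_QB, _QB],
        [1 - 2 * _QB, _QB],
        [_QB, 1 - 2 * _QB],
    ]
)
_QWTS = np.array([0.111690794839005] * 3 + [0.054975871827661] * 3)


def _basis(xi, eta):
    """Quadratic triangle basis: corners 0..2, midsides (01), (12), (20)."""
    l0 = 1.0 - xi - eta
    l1, l2 = xi, eta
    N = np.array(
        [
            l0 * (2 * l0 - 1),
            l1 * (2 * l1 - 1),
            l2 * (2 * l2 - 1),
            4 * l0 * l1,
            4 * l1 * l2,
            4 * l2 * l0,
        ]
    )
    dN = np.array(
        [
            [1 - 4 * l0, 1 - 4 * l0],
            [4 * l1 - 1, 0.0],
            [0.0, 4 * l2 - 1],
            [4 * (l0 - l1), -4 * l1],
            [4 * l2, 4 * l1],
            [-4 * l2, 4 * (l0 - l2)],
        ]
    )
    return N, dN


def surface_load_moment(mesh, scenario):
    """Mean stress of the applied surface loads (small-strain identity).

    Integrates ``t (x) x`` over the curved boundary, with the traction
    ``t = -p n_hat + tau`` evaluated from the scenario fields at each
    quadrature point, and divides by the enclosed volume (computed from
    the same surface via the divergence theorem).
    """
    faces = mesh.boundary_faces()
    assert faces.shape[1] == 6
    xs = mesh.nodes[faces]  # (k, 6, 3)

    moment = np.zeros((3, 3))
    volume = 0.0
    for (xi, eta), w in zip(_QPTS, _QWTS):
        N, dN = _basis(xi, eta)
        x = np.einsum("a,kai->ki", N, xs)
        a1 = np.einsum("a,kai->ki", dN[:, 0], xs)
        a2 = np.einsum("a,kai->ki", dN[:, 1], xs)
        nvec = np.cross(a1, a2)  # outward, |nvec| = dA/dxi deta
        da = np.linalg.norm(nvec, axis=1)
        nhat = nvec / da[:, None]
        xhat = x / np.linalg.norm(x, axis=1, keepdims=True)
        t = -scenario.pressure(xhat)[:, None] * nhat
        if scenario.traction is not None:
            t = t + scenario.traction(xhat)
        moment += w * np.einsum("ki,k,kj->ij", t, da, x)
        volume += w * np.einsum("ki,ki->", x, nvec) / 3.0
    mean = moment / volume
    return 0.5 * (mean + mean.T)
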