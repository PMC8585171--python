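import numpy as np
import pytest

from trabmech import BinaryVolume


@pytest.fixture
def plate_mask():
    """Two 5-voxel plates normal to z in a 24^3 grid, 0.1 mm spacing."""
    m = np.zeros((24, 24, 24), dtype=bool)
    m[2:7] = True
    m[14:19] = True
    return BinaryVolume(m, 0.1)


@pytest.fixture
def ball_mask():
    """Digital ball of radius 10 voxels, 0.1 mm spacing."""
    n, r = 26, 10
    z, y, x = np.mgrid[:n, :n, :n]
    c = n // 2
    return BinaryVolume((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= r * r,
                        0.1)


def dense_hex_solve(mesh, moduli, nu, dofs, vals):
    """Independent dense-matrix oracle for small voxel meshes.

    Re-derives the trilinear hexahedron stiffness from scratch with
    3x3x3 Gauss-Legendre quadrature and central-difference-free explicit
    shape-function gradients, assembles a dense global matrix and solves
    the constrained system with numpy.  Used to cross-check the sparse
    solver on tiny problems.
    """
    h = mesh.spacing
    corners = np.array([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
                        (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)],
                       dtype=float)
    gp, gw = np.polynomial.legendre.leggauss(3)

    def dshape(xi, eta, zeta):
        s = corners * 2.0 - 1.0
        g = np.empty((8, 3))
        for i, (sx, sy, sz) in enumerate(s):
            g[i, 0] = sx * (1 + sy * eta) * (1 + sz * zeta) / 8.0
            g[i, 1] = (1 + sx * xi) * sy * (1 + sz * zeta) / 8.0
            g[i, 2] = (1 + sx * xi) * (1 + sy * eta) * sz / 8.0
        return g * (2.0 / h)

    lam0 = nu / ((1 + nu) * (1 - 2 * nu))
    mu0 = 1.0 / (2 * (1 + nu))
    D1 = np.zeros((6, 6))
    D1[:3, :3] = lam0
    D1[np.diag_indices(3)] += 2 * mu0
    D1[3:, 3:] = np.eye(3) * mu0

    Ke1 = np.zeros((24, 24))
    detj = (h / 2.0) ** 3
    for a, wa in zip(gp, gw):
        for b, wb in zip(gp, gw):
            for c, wc in zip(gp, gw):
                dn = dshape(a, b, c)
                B = np.zeros((6, 24))
                for i in range(8):
                    bx, by, bz = dn[i]
                    col = 3 * i
                    B[0, col] = bx
                    B[1, col + 1] = by
                    B[2, col + 2] = bz
                    B[3, col], B[3, col + 1] = by, bx
                    B[4, col + 1], B[4, col + 2] = bz, by
                    B[5, col], B[5, col + 2] = bz, bx
                Ke1 += wa * wb * wc * (B.T @ D1 @ B) * detj

    ndof = 3 * mesh.n_nodes
    K = np.zeros((ndof, ndof))
    for e in range(mesh.n_elements):
        ed = np.repeat(mesh.elements[e] * 3, 3) + np.tile([0, 1, 2], 8)
        K[np.ix_(ed, ed)] += moduli[e] * Ke1
    u = np.zeros(ndof)
    u[dofs] = vals
    free = np.setdiff1d(np.arange(ndof), dofs)
    rhs = -K[np.ix_(free, dofs)] @ vals
    u[free] = np.linalg.solve(K[np.ix_(free, free)], rhs)
    return u
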