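"""Isoparametric element library: trilinear (8-node) and serendipity
quadratic (20-node) hexahedra plus their quadrilateral faces.

Node orderings follow the VTK conventions (VTK_HEXAHEDRON,
VTK_QUADRATIC_HEXAHEDRON, VTK_QUAD, VTK_QUADRATIC_QUAD).  All routines are
vectorised over elements; shapes are documented per function.
"""

from __future__ import annotations

import numpy as np

# corner coordinates, VTK hexahedron ordering
_HEX_CORNERS = np.array(
    [
        [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
    ],
    dtype=float,
)

# midside nodes, VTK quadratic hexahedron ordering (8..19)
_HEX_EDGES = np.array(
    [
        [0, -1, -1], [1, 0, -1], [0, 1, -1], [-1, 0, -1],
        [0, -1, 1], [1, 0, 1], [0, 1, 1], [-1, 0, 1],
        [-1, -1, 0], [1, -1, 0], [1, 1, 0], [-1, 1, 0],
    ],
    dtype=float,
)

HEX20_NODES = np.vstack([_HEX_CORNERS, _HEX_EDGES])


def gauss_rule_1d(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.legendre.leggauss(n)


def gauss_rule_hex(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Tensor-product Gauss rule: points (n^3, 3), weights (n^3,)."""
    x, w = gauss_rule_1d(n)
    P = np.array(np.meshgrid(x, x, x, indexing="ij")).reshape(3, -1).T
    W = np.prod(
        np.array(np.meshgrid(w, w, w, indexing="ij")).reshape(3, -1).T, axis=1
    )
    return P, W


def gauss_rule_quad(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = gauss_rule_1d(n)
    P = np.array(np.meshgrid(x, x, indexing="ij")).reshape(2, -1).T
    W = np.prod(np.array(np.meshgrid(w, w, indexing="ij")).reshape(2, -1).T, axis=1)
    return P, W


def hex8_shape(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear shape functions.

    Returns N (npt, 8) and dN (npt, 8, 3).
    """
    pts = np.atleast_2d(pts)
    xi, eta, zeta = pts[:, 0:1], pts[:, 1:2], pts[:, 2:3]
    xa, ya, za = _HEX_CORNERS.T
    N = 0.125 * (1 + xi * xa) * (1 + eta * ya) * (1 + zeta * za)
    dN = np.empty((pts.shape[0], 8, 3))
    dN[:, :, 0] = 0.125 * xa * (1 + eta * ya) * (1 + zeta * za)
    dN[:, :, 1] = 0.125 * ya * (1 + xi * xa) * (1 + zeta * za)
    dN[:, :, 2] = 0.125 * za * (1 + xi * xa) * (1 + eta * ya)
    return N, dN


def hex20_shape(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Serendipity quadratic shape functions.

    Returns N (npt, 20) and dN (npt, 20, 3).
    """
    pts = np.atleast_2d(pts)
    npt = pts.shape[0]
    N = np.empty((npt, 20))
    dN = np.empty((npt, 20, 3))
    xi, eta, zeta = pts[:, 0], pts[:, 1], pts[:, 2]
    for a in range(20):
        xa, ya, za = HEX20_NODES[a]
        if a < 8:  # corner
            f = (1 + xi * xa) * (1 + eta * ya) * (1 + zeta * za)
            g = xi * xa + eta * ya + zeta * za - 2.0
            N[:, a] = 0.125 * f * g
            dN[:, a, 0] = 0.125 * (
                xa * (1 + eta * ya) * (1 + zeta * za) * g + f * xa
            )
            dN[:, a, 1] = 0.125 * (
                ya * (1 + xi * xa) * (1 + zeta * za) * g + f * ya
            )
            dN[:, a, 2] = 0.125 * (
                za * (1 + xi * xa) * (1 + eta * ya) * g + f * za
            )
        elif xa == 0:
            N[:, a] = 0.25 * (1 - xi**2) * (1 + eta * ya) * (1 + zeta * za)
            dN[:, a, 0] = -0.5 * xi * (1 + eta * ya) * (1 + zeta * za)
            dN[:, a, 1] = 0.25 * (1 - xi**2) * ya * (1 + zeta * za)
            dN[:, a, 2] = 0.25 * (1 - xi**2) * (1 + eta * ya) * za
        elif ya == 0:
            N[:, a] = 0.25 * (1 + xi * xa) * (1 - eta**2) * (1 + zeta * za)
            dN[:, a, 0] = 0.25 * xa * (1 - eta**2) * (1 + zeta * za)
            dN[:, a, 1] = -0.5 * eta * (1 + xi * xa) * (1 + zeta * za)
            dN[:, a, 2] = 0.25 * (1 + xi * xa) * (1 - eta**2) * za
        else:
            N[:, a] = 0.25 * (1 + xi * xa) * (1 + eta * ya) * (1 - zeta**2)
            dN[:, a, 0] = 0.25 * xa * (1 + eta * ya) * (1 - zeta**2)
            dN[:, a, 1] = 0.25 * (1 + xi * xa) * ya * (1 - zeta**2)
            dN[:, a, 2] = -0.5 * zeta * (1 + xi * xa) * (1 + eta * ya)
    return N, dN


def quad4_shape(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pts = np.atleast_2d(pts)
    xi, eta = pts[:, 0:1], pts[:, 1:2]
    xa = np.array([-1, 1, 1, -1], dtype=float)
    ya = np.array([-1, -1, 1, 1], dtype=float)
    N = 0.25 * (1 + xi * xa) * (1 + eta * ya)
    dN = np.empty((pts.shape[0], 4, 2))
    dN[:, :, 0] = 0.25 * xa * (1 + eta * ya)
    dN[:, :, 1] = 0.25 * ya * (1 + xi * xa)
    return N, dN


_QUAD8_NODES = np.array(
    [[-1, -1], [1, -1], [1, 1], [-1, 1], [0, -1], [1, 0], [0, 1], [-1, 0]],
    dtype=float,
)


def quad8_shape(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pts = np.atleast_2d(pts)
    npt = pts.shape[0]
    N = np.empty((npt, 8))
    dN = np.empty((npt, 8, 2))
    xi, eta = pts[:, 0], pts[:, 1]
    for a in range(8):
        xa, ya = _QUAD8_NODES[a]
        if a < 4:
            f = (1 + xi * xa) * (1 + eta * ya)
            g = xi * xa + eta * ya - 1.0
            N[:, a] = 0.25 * f * g
            dN[:, a, 0] = 0.25 * (xa * (1 + eta * ya) * g + f * xa)
            dN[:, a, 1] = 0.25 * (ya * (1 + xi * xa) * g + f * ya)
        elif xa == 0:
            N[:, a] = 0.5 * (1 - xi**2) * (1 + eta * ya)
            dN[:, a, 0] = -xi * (1 + eta * ya)
            dN[:, a, 1] = 0.5 * (1 - xi**2) * ya
        else:
            N[:, a] = 0.5 * (1 + xi * xa) * (1 - eta**2)
            dN[:, a, 0] = 0.5 * xa * (1 - eta**2)
            dN[:, a, 1] = -eta * (1 + xi * xa)
    return N, dN


def shape_functions(order: int, nen: int | None = None):
    """(N, dN, gauss points, gauss weights) for a hex of given order."""
    if order == 1:
        gp, gw = gauss_rule_hex(2)
        N, dN = hex8_shape(gp)
    elif order == 2:
        gp, gw = gauss_rule_hex(3)
        N, dN = hex20_shape(gp)
    else:
        raise ValueError("order must be 1 or 2")
    return N, dN, gp, gw


def face_shape_functions(order: int, n_gauss: int = 4):
    if order == 1:
        gp, gw = gauss_rule_quad(n_gauss)
        N, dN = quad4_shape(gp)
    elif order == 2:
        gp, gw = gauss_rule_quad(n_gauss)
        N, dN = quad8_shape(gp)
    else:
        raise ValueError("order must be 1 or 2")
    return N, dN, gw


def jacobians(coords: np.ndarray, dN: np.ndarray):
    """Jacobians at each Gauss point of each element.

    coords: (ne, nen, 3); dN: (ngp, nen, 3).
    Returns detJ (ne, ngp) and gradN (ne, ngp, nen, 3) in physical coords.
    """
    J = np.einsum("eai,gaj->egji", coords, dN)  # J[e,g,j,i] = dx_i/dxi_j
    detJ = np.linalg.det(J)
    Jinv = np.linalg.inv(J)
    # dxi_j/dx_i = (J^-1)[i,j] (positional), so
    # gradN[e,g,a,i] = dN[g,a,j] * Jinv[e,g,i,j]
    gradN = np.einsum("gaj,egij->egai", dN, Jinv)
    return detJ, gradN


def scaled_jacobian(coords: np.ndarray, order: int) -> np.ndarray:
    """Min over Gauss points of det(J) scaled by the Jacobian column norms.

    1.0 for a cube; > 0 for a valid (possibly pole-collapsed) element.
    """
    _, dN, _, _ = shape_functions(order)
    J = np.einsum("eai,gaj->egji", coords, dN)
    detJ = np.linalg.det(J)
    norms = np.linalg.norm(J, axis=-1)  # row norms: |dx/dxi_j|
    denom = np.prod(norms, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sj = np.where(denom > 0, detJ / denom, 0.0)
    return sj.min(axis=1)
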