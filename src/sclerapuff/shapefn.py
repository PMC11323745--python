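"""Serendipity element shape functions and quadrature rules.

20-node quadratic hexahedra (VTK ordering: 8 corners, then 12 edge
midpoints) and their 8-node quadratic quadrilateral faces.  All routines
are vectorised over an array of local points.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "HEX20_LOCAL",
    "QUAD8_LOCAL",
    "FACE_INNER",
    "FACE_OUTER",
    "hex20_shape",
    "quad8_shape",
    "gauss_points",
]

_C = [
    (-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
    (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1),
]
_EDGES = [
    (0, 1), (1, 2), (2, 3), (3, 0),
    (4, 5), (5, 6), (6, 7), (7, 4),
    (0, 4), (1, 5), (2, 6), (3, 7),
]
#: local coordinates of the 20 nodes, VTK quadratic-hexahedron ordering
HEX20_LOCAL = np.array(
    _C + [tuple((np.array(_C[a]) + np.array(_C[b])) // 2) for a, b in _EDGES],
    dtype=float,
)

#: local coordinates of the 8 nodes of a quadratic quad face
QUAD8_LOCAL = np.array(
    [(-1, -1), (1, -1), (1, 1), (-1, 1), (0, -1), (1, 0), (0, 1), (-1, 0)],
    dtype=float,
)

#: parent-element node ids of the two radial faces, wound so that the face
#: tangent cross product points OUT of the solid shell
FACE_INNER = np.array([0, 3, 2, 1, 11, 10, 9, 8])
FACE_OUTER = np.array([4, 5, 6, 7, 12, 13, 14, 15])


def hex20_shape(pts: np.ndarray):
    """Shape functions and local gradients of the 20-node hexahedron.

    Parameters
    ----------
    pts : (Q, 3) array of local coordinates in [-1, 1]^3.

    Returns
    -------
    N : (Q, 20), dN : (Q, 20, 3)
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    q = pts.shape[0]
    N = np.empty((q, 20))
    dN = np.empty((q, 20, 3))
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    for a in range(20):
        xa, ya, za = HEX20_LOCAL[a]
        if xa and ya and za:  # corner
            f = (1 + x * xa) * (1 + y * ya) * (1 + z * za)
            g = x * xa + y * ya + z * za - 2.0
            N[:, a] = 0.125 * f * g
            dN[:, a, 0] = 0.125 * xa * (1 + y * ya) * (1 + z * za) * (g + (1 + x * xa))
            dN[:, a, 1] = 0.125 * ya * (1 + x * xa) * (1 + z * za) * (g + (1 + y * ya))
            dN[:, a, 2] = 0.125 * za * (1 + x * xa) * (1 + y * ya) * (g + (1 + z * za))
        else:  # edge midpoint: exactly one local coordinate is zero
            if xa == 0:
                N[:, a] = 0.25 * (1 - x * x) * (1 + y * ya) * (1 + z * za)
                dN[:, a, 0] = -0.5 * x * (1 + y * ya) * (1 + z * za)
                dN[:, a, 1] = 0.25 * (1 - x * x) * ya * (1 + z * za)
                dN[:, a, 2] = 0.25 * (1 - x * x) * (1 + y * ya) * za
            elif ya == 0:
                N[:, a] = 0.25 * (1 - y * y) * (1 + x * xa) * (1 + z * za)
                dN[:, a, 0] = 0.25 * (1 - y * y) * xa * (1 + z * za)
                dN[:, a, 1] = -0.5 * y * (1 + x * xa) * (1 + z * za)
                dN[:, a, 2] = 0.25 * (1 - y * y) * (1 + x * xa) * za
            else:
                N[:, a] = 0.25 * (1 - z * z) * (1 + x * xa) * (1 + y * ya)
                dN[:, a, 0] = 0.25 * (1 - z * z) * xa * (1 + y * ya)
                dN[:, a, 1] = 0.25 * (1 - z * z) * (1 + x * xa) * ya
                dN[:, a, 2] = -0.5 * z * (1 + x * xa) * (1 + y * ya)
    return N, dN


def quad8_shape(pts: np.ndarray):
    """Shape functions / gradients of the 8-node quadratic quadrilateral."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    q = pts.shape[0]
    N = np.empty((q, 8))
    dN = np.empty((q, 8, 2))
    x, y = pts[:, 0], pts[:, 1]
    for a in range(8):
        xa, ya = QUAD8_LOCAL[a]
        if xa and ya:  # corner
            N[:, a] = 0.25 * (1 + x * xa) * (1 + y * ya) * (x * xa + y * ya - 1)
            dN[:, a, 0] = 0.25 * xa * (1 + y * ya) * (2 * x * xa + y * ya)
            dN[:, a, 1] = 0.25 * ya * (1 + x * xa) * (x * xa + 2 * y * ya)
        elif xa == 0:
            N[:, a] = 0.5 * (1 - x * x) * (1 + y * ya)
            dN[:, a, 0] = -x * (1 + y * ya)
            dN[:, a, 1] = 0.5 * (1 - x * x) * ya
        else:
            N[:, a] = 0.5 * (1 + x * xa) * (1 - y * y)
            dN[:, a, 0] = 0.5 * xa * (1 - y * y)
            dN[:, a, 1] = -y * (1 + x * xa)
    return N, dN


def gauss_points(n: int, dim: int):
    """Tensor-product Gauss-Legendre rule: (points (n^dim, dim), weights)."""
    x, w = np.polynomial.legendre.leggauss(n)
    grids = np.meshgrid(*([x] * dim), indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=-1)
    wgrids = np.meshgrid(*([w] * dim), indexing="ij")
    wts = np.ones(pts.shape[0])
    for g in wgrids:
        wts *= g.ravel()
    return pts, wts
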