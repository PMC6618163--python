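"""Shared piecewise-linear (P1) tetrahedral finite-element primitives.

All assembly here is vectorized over elements with einsum; meshes at the
scales this package targets (10^2-10^4 cells) never need compiled kernels.
"""
from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def cell_volumes_and_gradients(vertices: np.ndarray, cells: np.ndarray):
    """Signed volumes (m,) and P1 shape-function gradients (m, 4, 3).

    Gradient rows are ordered like the cell's vertices; they satisfy
    sum_a grad_a = 0 and grad_a . (x_b - x_a) = -1 for b != a.
    """
    x = vertices[cells]                      # (m, 4, 3)
    e = x[:, 1:] - x[:, :1]                  # (m, 3, 3) edge matrix rows
    vol = np.linalg.det(e) / 6.0
    # gradients of barycentric coords 1..3 are rows of inv(e)^T
    einv = np.linalg.inv(e)                  # (m, 3, 3)
    g123 = np.swapaxes(einv, 1, 2)           # (m, 3, 3): grad of lambda_1..3
    g0 = -g123.sum(axis=1, keepdims=True)
    return vol, np.concatenate([g0, g123], axis=1)


def assemble_stiffness(vertices: np.ndarray, cells: np.ndarray) -> sp.csr_matrix:
    """P1 Laplace stiffness matrix (n x n), exact for linear fields."""
    vol, grads = cell_volumes_and_gradients(vertices, cells)
    ke = np.einsum("e,eai,ebi->eab", vol, grads, grads)
    rows = np.repeat(cells, 4, axis=1).ravel()
    cols = np.tile(cells, (1, 4)).ravel()
    n = len(vertices)
    return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def assemble_mass(vertices: np.ndarray, cells: np.ndarray) -> sp.csr_matrix:
    """Consistent P1 mass matrix: M_e = (V/20) (1 + delta_ab)."""
    vol, _ = cell_volumes_and_gradients(vertices, cells)
    base = (np.ones((4, 4)) + np.eye(4)) / 20.0
    ke = vol[:, None, None] * base[None]
    rows = np.repeat(cells, 4, axis=1).ravel()
    cols = np.tile(cells, (1, 4)).ravel()
    n = len(vertices)
    return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def facet_areas_and_normals(vertices: np.ndarray, facets: np.ndarray):
    """Areas (k,) and unit normals (k, 3) of boundary triangles.

    The normal follows the right-hand rule on the stored vertex order, which
    for facets extracted by :func:`boundary_facets` points out of the domain.
    """
    x = vertices[facets]
    cr = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
    area2 = np.linalg.norm(cr, axis=1)
    return area2 / 2.0, cr / area2[:, None]


def lumped_facet_vertex_areas(n_vertices: int, vertices, facets) -> np.ndarray:
    """Nodal areas: one third of each adjacent facet's area per vertex."""
    areas, _ = facet_areas_and_normals(vertices, facets)
    out = np.zeros(n_vertices)
    np.add.at(out, facets.ravel(), np.repeat(areas / 3.0, 3))
    return out


def boundary_facets(cells: np.ndarray) -> np.ndarray:
    """Boundary triangles of a tet mesh, outward-oriented.

    For a positively oriented tet (a, b, c, d) the four outward faces are
    (b, c, d), (a, d, c), (a, b, d), (a, c, b); faces occurring once in the
    mesh are on the boundary.
    """
    f = np.concatenate(
        [
            cells[:, [1, 2, 3]],
            cells[:, [0, 3, 2]],
            cells[:, [0, 1, 3]],
            cells[:, [0, 2, 1]],
        ]
    )
    key = np.sort(f, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return f[counts[inv] == 1]


def interior_face_check(cells: np.ndarray) -> bool:
    """True iff every face is shared by at most two tets (conforming mesh)."""
    f = np.concatenate(
        [cells[:, [1, 2, 3]], cells[:, [0, 2, 3]], cells[:, [0, 1, 3]], cells[:, [0, 1, 2]]]
    )
    _, counts = np.unique(np.sort(f, axis=1), axis=0, return_counts=True)
    return bool(counts.max() <= 2)
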