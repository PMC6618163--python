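"""Rule-based myocardial fiber architecture.

A harmonic transmural coordinate t (0 on the endocardium, 1 on the
epicardium) is computed by a Laplace solve; local wall axes
(circumferential, longitudinal, transmural) follow from its gradient and
the apex-base direction; and the fiber/sheet/sheet-normal triad is obtained
by rotating the circumferential axis by the helix angle alpha(t) in the
circumferential-longitudinal plane, then rotating the sheet pair about the
fiber axis by the transverse angle beta(t). Both angles interpolate
linearly in t between their endocardial and epicardial values.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._fem import assemble_stiffness, cell_volumes_and_gradients
from .geometry import ENDO, EPI, Mesh

logger = logging.getLogger(__name__)

_ORTHO_TOL = 1e-10


class FiberAngleError(ValueError):
    """A fiber angle lies outside the admissible range (-90, 90] degrees."""


@dataclass(frozen=True)
class AngleBC:
    """Helix (alpha) and transverse (beta) angles on the two surfaces, degrees."""

    alpha_endo: float = 50.0
    alpha_epi: float = -50.0
    beta_endo: float = -65.0
    beta_epi: float = 25.0

    def __post_init__(self):
        # (-90, 90] is the fundamental domain of an (unsigned) fiber
        # direction, but random draws from the angle distributions can fall
        # slightly outside it; rotations remain well defined there, so only
        # angles beyond a half turn are rejected.
        for name in ("alpha_endo", "alpha_epi", "beta_endo", "beta_epi"):
            v = getattr(self, name)
            if not (-180.0 < v <= 180.0):
                raise FiberAngleError(f"{name}={v} outside (-180, 180] degrees")


@dataclass
class TransmuralField:
    """Nodal transmural coordinate: 0 on endo, 1 on epi."""

    values: np.ndarray

    def validate(self, mesh: Mesh) -> None:
        if np.abs(self.values[mesh.vertices_of(ENDO)]).max() > _ORTHO_TOL:
            raise ValueError("transmural coordinate nonzero on endocardium")
        if np.abs(self.values[mesh.vertices_of(EPI)] - 1).max() > _ORTHO_TOL:
            raise ValueError("transmural coordinate != 1 on epicardium")
        if self.values.min() < -_ORTHO_TOL or self.values.max() > 1 + _ORTHO_TOL:
            raise ValueError("transmural coordinate escapes [0, 1]")


@dataclass
class FiberFrameField:
    """Orthonormal right-handed (fiber, sheet, sheet-normal) triads per vertex."""

    f: np.ndarray
    s: np.ndarray
    n: np.ndarray

    def as_matrix(self) -> np.ndarray:
        """(n, 3, 3) rotation matrices with columns (f, s, n)."""
        return np.stack([self.f, self.s, self.n], axis=-1)

    def validate(self) -> None:
        R = self.as_matrix()
        gram = np.einsum("vij,vik->vjk", R, R)
        if np.abs(gram - np.eye(3)).max() > _ORTHO_TOL:
            raise ValueError("fiber triads are not orthonormal")
        if np.abs(np.cross(self.f, self.s) - self.n).max() > 1e-8:
            raise ValueError("fiber triads are not right-handed (f x s != n)")


def solve_transmural_coordinate(mesh: Mesh) -> TransmuralField:
    """Discrete harmonic function: 0 on endo, 1 on epi, zero flux on base."""
    endo, epi = mesh.vertices_of(ENDO), mesh.vertices_of(EPI)
    if len(endo) == 0 or len(epi) == 0:
        raise ValueError("mesh is missing endo or epi facet labels")
    K = assemble_stiffness(mesh.vertices, mesh.cells)
    n = mesh.n_vertices
    fixed = np.zeros(n, bool)
    fixed[endo] = fixed[epi] = True
    g = np.zeros(n)
    g[epi] = 1.0
    free = ~fixed
    rhs = -K[free][:, fixed] @ g[fixed]
    t = g.copy()
    t[free] = spla.spsolve(K[free][:, free].tocsc(), rhs)
    return TransmuralField(values=t)


def _vertex_gradient(mesh: Mesh, nodal: np.ndarray) -> np.ndarray:
    """Volume-weighted average of the per-cell P1 gradient at each vertex."""
    vol, grads = cell_volumes_and_gradients(mesh.vertices, mesh.cells)
    gcell = np.einsum("eai,ea->ei", grads, nodal[mesh.cells])
    acc = np.zeros((mesh.n_vertices, 3))
    wacc = np.zeros(mesh.n_vertices)
    np.add.at(acc, mesh.cells.ravel(), np.repeat(gcell * vol[:, None], 4, axis=0))
    np.add.at(wacc, mesh.cells.ravel(), np.repeat(vol, 4))
    return acc / wacc[:, None]


def local_axes(mesh: Mesh, t: TransmuralField, apex_radius: float | None = None):
    """(circumferential, longitudinal, transmural) unit vectors per vertex.

    The transmural axis is the normalized gradient of t; the longitudinal
    axis is the apex-base direction (+z) projected orthogonal to it; the
    circumferential axis completes the right-handed triad. Near the long
    axis the projection degenerates, so vertices inside a small cylinder
    around the axis inherit the longitudinal axis of their nearest
    well-defined neighbor (logged).
    """
    grad = _vertex_gradient(mesh, t.values)
    gnorm = np.linalg.norm(grad, axis=1)
    e_t = grad / np.where(gnorm > 0, gnorm, 1.0)[:, None]

    zhat = np.array([0.0, 0.0, 1.0])
    proj = zhat - e_t * e_t[:, 2:3]
    pnorm = np.linalg.norm(proj, axis=1)

    if apex_radius is None:
        # default: twice the typical in-plane vertex spacing near the apex
        r = np.hypot(mesh.vertices[:, 0], mesh.vertices[:, 1])
        apex_radius = 2.0 * np.partition(r[r > 1e-12], 8)[8]
    r_cyl = np.hypot(mesh.vertices[:, 0], mesh.vertices[:, 1])
    bad = (pnorm < 1e-6) | (gnorm == 0) | (r_cyl < apex_radius)
    if bad.any():
        logger.info("local_axes: %d apex/degenerate vertices use neighbor fallback", bad.sum())
        good = np.where(~bad)[0]
        from scipy.spatial import cKDTree

        tree = cKDTree(mesh.vertices[good])
        _, idx = tree.query(mesh.vertices[bad])
        donor = proj[good[idx]]
        # re-project the donor direction orthogonal to the local transmural axis
        donor = donor - e_t[bad] * np.einsum("ij,ij->i", donor, e_t[bad])[:, None]
        proj[bad] = donor
        pnorm = np.linalg.norm(proj, axis=1)
        if pnorm.min() <= 0:
            raise RuntimeError("longitudinal axis undefined even after fallback")
    e_l = proj / pnorm[:, None]
    e_c = np.cross(e_l, e_t)
    return e_c, e_l, e_t


def assign_fiber_frame(mesh: Mesh, t: TransmuralField, angles: AngleBC) -> FiberFrameField:
    """Build the fiber/sheet/sheet-normal frame from transmurally
    interpolated helix and transverse angles."""
    e_c, e_l, e_t = local_axes(mesh, t)
    tv = t.values[:, None]
    alpha = np.deg2rad((1 - tv) * angles.alpha_endo + tv * angles.alpha_epi)
    beta = np.deg2rad((1 - tv) * angles.beta_endo + tv * angles.beta_epi)

    f = np.cos(alpha) * e_c + np.sin(alpha) * e_l
    # sheet pair: start from the transmural axis projected off f, rotate by beta
    s0 = e_t - f * np.einsum("ij,ij->i", e_t, f)[:, None]
    s0 /= np.linalg.norm(s0, axis=1)[:, None]
    n0 = np.cross(f, s0)
    s = np.cos(beta) * s0 + np.sin(beta) * n0
    n = np.cross(f, s)
    frame = FiberFrameField(f=f, s=s, n=n)
    frame.validate()
    return frame


def helix_angle(frame: FiberFrameField, mesh: Mesh, t: TransmuralField) -> np.ndarray:
    """Recover the helix angle (degrees) by projecting f onto the local axes."""
    e_c, e_l, _ = local_axes(mesh, t)
    return np.rad2deg(
        np.arctan2(np.einsum("ij,ij->i", frame.f, e_l), np.einsum("ij,ij->i", frame.f, e_c))
    )
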