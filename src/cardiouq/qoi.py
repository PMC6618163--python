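"""Global response quantities of the deformed ventricle.

Four scalar outputs characterize the deformation: cavity volume Q_c (cm^3),
apex lengthening Q_l (cm, epicardial minus endocardial axial length), wall
thickness at the base Q_t (cm, mean outer minus inner basal radius), and
wall volume Q_v (cm^3). All four are invariant under rigid-body motions
appended to the displacement field.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fem import cell_volumes_and_gradients
from .geometry import BASE, ENDO, EPI, Mesh
from .mechanics import DisplacementField, NonPhysicalStateError, _det3


class GeometryError(RuntimeError):
    """The mesh lacks a feature needed by a quantity of interest."""


@dataclass(frozen=True)
class QoISet:
    """The four global quantities of interest, in cm-based units."""

    Q_c: float   # cavity volume, cm^3
    Q_l: float   # apex lengthening, cm
    Q_t: float   # wall thickness at base, cm
    Q_v: float   # wall volume, cm^3

    def as_array(self) -> np.ndarray:
        return np.array([self.Q_c, self.Q_l, self.Q_t, self.Q_v])

    NAMES = ("Q_c", "Q_l", "Q_t", "Q_v")


def _deformed(mesh: Mesh, u: DisplacementField) -> np.ndarray:
    return mesh.vertices + u.u


def _basal_ring(mesh: Mesh, tag: int) -> np.ndarray:
    """Vertices on both the given surface and the base, ordered by angle."""
    ring = np.intersect1d(mesh.vertices_of(tag), mesh.vertices_of(BASE))
    if len(ring) == 0:
        raise GeometryError("no basal boundary vertices found")
    xy = mesh.vertices[ring, :2] - mesh.vertices[ring, :2].mean(axis=0)
    return ring[np.argsort(np.arctan2(xy[:, 1], xy[:, 0]))]


def cavity_volume(mesh: Mesh, u: DisplacementField) -> float:
    """Volume enclosed by the deformed endocardium and its basal cap.

    The open basal rim is closed by a triangle fan about the deformed basal
    endocardial centroid and the volume computed by the divergence theorem
    over the resulting watertight surface.
    """
    x = _deformed(mesh, u)
    endo = mesh.facets_of(ENDO)
    ring = _basal_ring(mesh, ENDO)
    centroid = x[ring].mean(axis=0)
    rim = x[ring]
    nxt = np.roll(rim, -1, axis=0)
    # endo facets are outward for the solid = inward for the cavity: the
    # divergence-theorem sum then comes out negative, flip at the end.
    tri = x[endo]
    v = _det3(np.stack([tri[:, 0], tri[:, 1], tri[:, 2]], axis=1)).sum()
    cap = _det3(np.stack(
        [np.broadcast_to(centroid, rim.shape), nxt, rim], axis=1)).sum()
    vol = -(v + cap) / 6.0
    if vol <= 0:
        raise GeometryError(
            "cavity closure produced a non-positive volume (non-watertight "
            "endocardial surface?)"
        )
    return float(vol)


def apex_lengthening(mesh: Mesh, u: DisplacementField) -> float:
    """Deformed epicardial minus endocardial apex-to-base axial length.

    The apexes are tracked materially: the vertices that are extremal along
    the long axis on each surface in the reference configuration.
    """
    x = _deformed(mesh, u)
    i_epi = mesh.vertices_of(EPI)[np.argmin(mesh.vertices[mesh.vertices_of(EPI), 2])]
    i_endo = mesh.vertices_of(ENDO)[np.argmin(mesh.vertices[mesh.vertices_of(ENDO), 2])]
    z_base = x[mesh.vertices_of(BASE), 2].mean()
    return float((z_base - x[i_epi, 2]) - (z_base - x[i_endo, 2]))


def wall_thickness_at_base(mesh: Mesh, u: DisplacementField) -> float:
    """Mean deformed outer minus inner radius over the basal rings.

    Radii are measured in the basal plane about the deformed centroid of
    all basal boundary vertices, making the measure translation invariant.
    """
    x = _deformed(mesh, u)
    base_v = mesh.vertices_of(BASE)
    center = x[base_v, :2].mean(axis=0)
    r_out = np.linalg.norm(x[_basal_ring(mesh, EPI), :2] - center, axis=1).mean()
    r_in = np.linalg.norm(x[_basal_ring(mesh, ENDO), :2] - center, axis=1).mean()
    return float(r_out - r_in)


def wall_volume(mesh: Mesh, u: DisplacementField) -> float:
    """Deformed wall volume: integral of J over the reference domain."""
    vol, grads = cell_volumes_and_gradients(mesh.vertices, mesh.cells)
    F = np.eye(3) + np.einsum("eai,eaj->eji", grads, u.u[mesh.cells])
    J = _det3(F)
    if np.any(J <= 0):
        raise NonPhysicalStateError("deformation inverts an element (J <= 0)")
    return float((vol * J).sum())


def compute_qois(mesh: Mesh, u: DisplacementField) -> QoISet:
    return QoISet(
        Q_c=cavity_volume(mesh, u),
        Q_l=apex_lengthening(mesh, u),
        Q_t=wall_thickness_at_base(mesh, u),
        Q_v=wall_volume(mesh, u),
    )
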