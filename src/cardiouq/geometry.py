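"""Idealized left-ventricle geometry: a truncated prolate ellipsoid shell.

The ventricle wall is the region between two coaxial ellipsoids of
revolution sharing a center on the long axis, cut by a flat basal plane.
Coordinates are in cm with the epicardial apex at the origin and the long
axis along +z; the basal plane sits at ``z = base_cut_height``.

The default dimensions are calibrated (see
:func:`calibrate_reference_geometry`) so that the undeformed reference
quantities of interest match the reference values used throughout the
package: cavity volume 170 cm^3, wall volume 126 cm^3, apical wall
thickness 1.11 cm and basal wall thickness 0.699 cm.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import brentq
from scipy.sparse.csgraph import connected_components

from ._fem import boundary_facets, cell_volumes_and_gradients, interior_face_check

ENDO, EPI, BASE = 1, 2, 3
FACET_TAG_NAMES = {ENDO: "endo", EPI: "epi", BASE: "base"}

#: Reference quantities of interest of the undeformed ventricle
#: (cavity volume cm^3, apical thickness cm, basal thickness cm, wall volume cm^3).
REFERENCE_QOIS = {"Q_c": 170.0, "Q_l": 1.11, "Q_t": 0.699, "Q_v": 126.0}


class ConfigurationError(ValueError):
    """A geometry configuration violates one of its invariants."""


class MeshIOError(IOError):
    """A mesh file is unreadable or missing a required component."""


@dataclass(frozen=True)
class LVGeometryConfig:
    """Parameters of the truncated-ellipsoid left-ventricle shell.

    Semi-axes are (a, b, c) with c along the long axis; both ellipsoids
    share their center at ``z = epi_semi_axes[2]`` so the epicardial apex
    touches the origin.
    """

    endo_semi_axes: tuple[float, float, float] = (2.706954402, 2.706954402, 8.137564709)
    epi_semi_axes: tuple[float, float, float] = (3.403474973, 3.403474973, 9.247564709)
    base_cut_height: float = 11.247564709
    target_edge_length: float = 0.88
    long_axis_convention: str = "z"

    def __post_init__(self):
        self.validate()

    @property
    def center_z(self) -> float:
        return self.epi_semi_axes[2]

    @property
    def cut_offset(self) -> float:
        """Height of the basal cut above the shared ellipsoid center."""
        return self.base_cut_height - self.center_z

    def validate(self) -> None:
        en, ep = np.asarray(self.endo_semi_axes, float), np.asarray(self.epi_semi_axes, float)
        if self.long_axis_convention != "z":
            raise ConfigurationError("long_axis_convention: only 'z' is supported")
        if not np.all(en > 0):
            raise ConfigurationError("endo_semi_axes must be strictly positive")
        if not np.all(ep > en):
            raise ConfigurationError(
                "epi_semi_axes must strictly exceed endo_semi_axes component-wise "
                "(zero or negative wall thickness)"
            )
        if self.target_edge_length <= 0:
            raise ConfigurationError("target_edge_length must be positive")
        hp = self.cut_offset
        if not (-en[2] < hp < en[2]):
            raise ConfigurationError(
                "base_cut_height: the basal plane must intersect both ellipsoids "
                f"(cut offset {hp:.3g} outside inner ellipsoid span +-{en[2]:.3g})"
            )

    def refined(self, factor: float = 2.0) -> "LVGeometryConfig":
        """Copy with the target edge length divided by ``factor``."""
        return dataclasses.replace(self, target_edge_length=self.target_edge_length / factor)


@dataclass
class Mesh:
    """Tetrahedral mesh with labeled boundary triangles.

    ``facets`` are outward-oriented boundary triangles; ``facet_tags`` holds
    one of the integers ENDO (1), EPI (2), BASE (3) per facet.
    """

    vertices: np.ndarray          # (n, 3) float64, cm
    cells: np.ndarray             # (m, 4) int
    facets: np.ndarray            # (k, 3) int
    facet_tags: np.ndarray        # (k,) int

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def facets_of(self, tag: int) -> np.ndarray:
        return self.facets[self.facet_tags == tag]

    def vertices_of(self, tag: int) -> np.ndarray:
        """Sorted unique vertex indices on the given boundary surface."""
        return np.unique(self.facets_of(tag))

    def cell_volumes(self) -> np.ndarray:
        vol, _ = cell_volumes_and_gradients(self.vertices, self.cells)
        return vol

    def wall_volume(self) -> float:
        return float(self.cell_volumes().sum())

    def validate(self) -> None:
        vol = self.cell_volumes()
        if not np.all(vol > 0):
            raise ValueError(f"{(vol <= 0).sum()} cells have non-positive volume")
        bf = boundary_facets(self.cells)
        if len(bf) != len(self.facets):
            raise ValueError("facet_labels do not cover the mesh boundary")
        if set(np.unique(self.facet_tags)) - set(FACET_TAG_NAMES):
            raise ValueError("facet_labels contain an unknown tag")
        if not interior_face_check(self.cells):
            raise ValueError("mesh is not conforming: a face is shared by >2 cells")
        adj = sp.coo_matrix(
            (
                np.ones(len(self.cells) * 3),
                (self.cells[:, [0, 1, 2]].ravel(), self.cells[:, [1, 2, 3]].ravel()),
            ),
            shape=(self.n_vertices, self.n_vertices),
        )
        ncomp, _ = connected_components(adj, directed=False)
        if ncomp != 1:
            raise ValueError(f"mesh has {ncomp} connected components, expected 1")


# ---------------------------------------------------------------------------
# analytic volumes and calibration
# ---------------------------------------------------------------------------

def _cap_volume(a: float, b: float, c: float, hp: float) -> float:
    """Volume of an ellipsoid cap from the apex z=-c up to z=hp (center 0)."""
    hp = min(hp, c)
    return float(np.pi * a * b * (hp - hp**3 / (3 * c**2) + 2 * c / 3))


def analytic_shell_volume(config: LVGeometryConfig) -> float:
    """Exact volume of the truncated ellipsoidal shell (cm^3)."""
    config.validate()
    a_en, b_en, c_en = config.endo_semi_axes
    a_ep, b_ep, c_ep = config.epi_semi_axes
    hp = config.cut_offset
    return _cap_volume(a_ep, b_ep, c_ep, hp) - _cap_volume(a_en, b_en, c_en, hp)


def analytic_cavity_volume(config: LVGeometryConfig) -> float:
    """Exact inner-cavity volume below the basal plane (cm^3)."""
    a, b, c = config.endo_semi_axes
    return _cap_volume(a, b, c, config.cut_offset)


def calibrate_reference_geometry(
    cavity_volume: float = REFERENCE_QOIS["Q_c"],
    wall_volume: float = REFERENCE_QOIS["Q_v"],
    apical_thickness: float = REFERENCE_QOIS["Q_l"],
    basal_thickness: float = REFERENCE_QOIS["Q_t"],
    cut_offset: float = 2.0,
    **config_kwargs,
) -> LVGeometryConfig:
    """Solve for ellipsoid semi-axes matching the four reference quantities.

    With a circular cross-section and a prescribed cut height above the
    shared center, the four constraints reduce to a scalar root-find in the
    inner equatorial radius: the inner long semi-axis follows from the
    cavity volume, the outer axes from the thickness constraints, and the
    residual is the wall-volume mismatch.
    """

    def solve_c(a: float, volume: float) -> float:
        return brentq(lambda c: _cap_volume(a, a, c, cut_offset) - volume,
                      cut_offset + 1e-9, 1000.0, xtol=1e-13)

    def chain(a_en: float):
        c_en = solve_c(a_en, cavity_volume)
        c_ep = c_en + apical_thickness
        r_en = a_en * np.sqrt(1 - cut_offset**2 / c_en**2)
        a_ep = (basal_thickness + r_en) / np.sqrt(1 - cut_offset**2 / c_ep**2)
        resid = (_cap_volume(a_ep, a_ep, c_ep, cut_offset)
                 - cavity_volume - wall_volume)
        return resid, (a_en, c_en, a_ep, c_ep)

    # the cap volume at fixed a is minimized as c -> cut_offset, which caps
    # the admissible inner radius; bracket the root inside that range
    a_max = np.sqrt(
        cavity_volume
        / (np.pi * (cut_offset - cut_offset / 3 + 2 * cut_offset / 3))
    ) * (1.0 - 1e-9)
    grid = np.linspace(0.3 * a_max, a_max, 80)
    vals = []
    for a in grid:
        try:
            vals.append(chain(a)[0])
        except ValueError:
            vals.append(np.nan)
    sign_change = [
        (grid[i], grid[i + 1])
        for i in range(len(grid) - 1)
        if np.isfinite(vals[i]) and np.isfinite(vals[i + 1])
        and np.sign(vals[i]) != np.sign(vals[i + 1])
    ]
    if not sign_change:
        raise ConfigurationError("calibration targets admit no ellipsoid solution")
    a_en = brentq(lambda a: chain(a)[0], *sign_change[0], xtol=1e-12)
    _, (a_en, c_en, a_ep, c_ep) = chain(a_en)
    return LVGeometryConfig(
        endo_semi_axes=(a_en, a_en, c_en),
        epi_semi_axes=(a_ep, a_ep, c_ep),
        base_cut_height=c_ep + cut_offset,
        **config_kwargs,
    )


# ---------------------------------------------------------------------------
# mesh generation
# ---------------------------------------------------------------------------

def _resolution(config: LVGeometryConfig) -> tuple[int, int, int]:
    """(n_circ, n_long, n_trans) derived from the target edge length."""
    ell = config.target_edge_length
    a_en, _, c_en = config.endo_semi_axes
    a_ep, _, c_ep = config.epi_semi_axes
    hp = config.cut_offset
    r_base = 0.5 * (
        a_en * np.sqrt(1 - hp**2 / c_en**2) + a_ep * np.sqrt(1 - hp**2 / c_ep**2)
    )
    n_circ = max(8, int(round(2 * np.pi * r_base / ell)))
    # mid-surface meridian arc length, sampled numerically
    u = np.linspace(0.0, 1.0, 200)
    p_en = _surface_points(config.endo_semi_axes, config.center_z, hp, u, np.zeros_like(u))
    p_ep = _surface_points(config.epi_semi_axes, config.center_z, hp, u, np.zeros_like(u))
    mid = 0.5 * (p_en + p_ep)
    arc = np.linalg.norm(np.diff(mid, axis=0), axis=1).sum()
    n_long = max(4, int(round(arc / ell)))
    thickness = a_ep * np.sqrt(1 - hp**2 / c_ep**2) - a_en * np.sqrt(1 - hp**2 / c_en**2)
    n_trans = max(2, int(round(thickness / ell)))
    return n_circ, n_long, n_trans


def _surface_points(semi_axes, z0, hp, u_frac, phi):
    """Points on one ellipsoid surface; u_frac in [0,1] from apex to cut."""
    a, b, c = semi_axes
    u_cut = np.arccos(np.clip(-hp / c, -1.0, 1.0))
    u = u_frac * u_cut
    x, y, z = np.broadcast_arrays(
        a * np.sin(u) * np.cos(phi), b * np.sin(u) * np.sin(phi), z0 - c * np.cos(u)
    )
    return np.stack([x, y, z], axis=-1)


def build_idealized_lv(config: LVGeometryConfig) -> Mesh:
    """Generate the labeled tetrahedral mesh of the truncated shell.

    A structured (transmural x meridional x circumferential) vertex grid is
    blended linearly between the two ellipsoid surfaces and tetrahedralized
    with the index-space Kuhn subdivision, whose translation-invariant
    diagonal pattern keeps the mesh conforming; hexahedra collapsed at the
    apex pole degenerate into prisms whose zero-volume tets are dropped.
    """
    config.validate()
    n_circ, n_long, n_trans = _resolution(config)
    z0, hp = config.center_z, config.cut_offset

    phi = 2 * np.pi * np.arange(n_circ) / n_circ
    u_frac = np.arange(n_long + 1) / n_long
    s = np.arange(n_trans + 1) / n_trans

    # vertex ids: pole vertex per layer, then (layer, ring j>=1, k)
    n_ring_pts = n_long * n_circ + 1
    def vid(i_s, j, k):
        if j == 0:
            return i_s * n_ring_pts
        return i_s * n_ring_pts + 1 + (j - 1) * n_circ + (k % n_circ)

    verts = np.empty(((n_trans + 1) * n_ring_pts, 3))
    layer_of = np.empty(len(verts), int)
    for i_s, sv in enumerate(s):
        p_en = _surface_points(config.endo_semi_axes, z0, hp, u_frac[:, None], phi[None, :])
        p_ep = _surface_points(config.epi_semi_axes, z0, hp, u_frac[:, None], phi[None, :])
        p = (1 - sv) * p_en + sv * p_ep      # (n_long+1, n_circ, 3)
        verts[vid(i_s, 0, 0)] = p[0, 0]
        for j in range(1, n_long + 1):
            for k in range(n_circ):
                verts[vid(i_s, j, k)] = p[j, k]
        layer_of[i_s * n_ring_pts:(i_s + 1) * n_ring_pts] = i_s
    ring_of = np.empty(len(verts), int)
    for i_s in range(n_trans + 1):
        ring_of[vid(i_s, 0, 0)] = 0
        for j in range(1, n_long + 1):
            for k in range(n_circ):
                ring_of[vid(i_s, j, k)] = j

    # Kuhn 6-tet split of each index-space hex (i_s, j, k)
    perms = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]
    axes = np.eye(3, dtype=int)
    cells = []
    for i_s in range(n_trans):
        for j in range(n_long):
            for k in range(n_circ):
                corner = np.array([i_s, j, k])
                for p3 in perms:
                    path = [corner.copy()]
                    for ax in p3:
                        path.append(path[-1] + axes[ax])
                    ids = [vid(q[0], q[1], q[2]) for q in path]
                    if len(set(ids)) == 4:
                        cells.append(ids)
    cells = np.asarray(cells, dtype=np.int64)

    # orient positively, drop exact degenerates produced by the pole collapse
    vol, _grads = _volumes(verts, cells)
    flip = vol < 0
    cells[flip] = cells[flip][:, [1, 0, 2, 3]]
    vol = np.abs(vol)
    keep = vol > 1e-12 * np.median(vol[vol > 0])
    cells = cells[keep]

    facets = boundary_facets(cells)
    tags = _classify_facets(facets, layer_of, ring_of, n_trans, n_long)
    mesh = Mesh(vertices=verts, cells=cells, facets=facets, facet_tags=tags)
    mesh.validate()
    _check_surface_fit(mesh, config)
    return mesh


def _volumes(verts, cells):
    x = verts[cells]
    e = x[:, 1:] - x[:, :1]
    return np.linalg.det(e) / 6.0, None


def _classify_facets(facets, layer_of, ring_of, n_trans, n_long):
    lay = layer_of[facets]
    ring = ring_of[facets]
    tags = np.zeros(len(facets), int)
    tags[np.all(ring == n_long, axis=1)] = BASE
    unset = tags == 0
    tags[unset & np.all(lay == 0, axis=1)] = ENDO
    unset = tags == 0
    tags[unset & np.all(lay == n_trans, axis=1)] = EPI
    if np.any(tags == 0):
        raise RuntimeError("unclassifiable boundary facet (mesh generation bug)")
    return tags


def _check_surface_fit(mesh: Mesh, config: LVGeometryConfig) -> None:
    """Endo/epi facet vertices must sit on their ellipsoids, base on the cut."""
    tol = config.target_edge_length / 10.0
    for tag, axes in ((ENDO, config.endo_semi_axes), (EPI, config.epi_semi_axes)):
        v = mesh.vertices[mesh.vertices_of(tag)]
        rel = (v - [0, 0, config.center_z]) / axes
        # distance to the ellipsoid along the radial parameter, scaled back
        lvl = np.linalg.norm(rel, axis=1)
        dist = np.abs(lvl - 1.0) * min(axes)
        if dist.max() > tol:
            raise RuntimeError(f"{FACET_TAG_NAMES[tag]} vertices off surface by {dist.max():.3g} cm")
    vb = mesh.vertices[mesh.vertices_of(BASE)]
    if np.abs(vb[:, 2] - config.base_cut_height).max() > 1e-8:
        raise RuntimeError("base vertices off the basal plane")


# ---------------------------------------------------------------------------
# mesh I/O (Gmsh MSH 2.2 ASCII)
# ---------------------------------------------------------------------------

_MSH_TRI, _MSH_TET = 2, 4


def write_mesh(mesh: Mesh, path) -> None:
    """Serialize to Gmsh MSH 2.2 ASCII with facet labels as physical tags."""
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$PhysicalNames", "3"]
    for tag, name in FACET_TAG_NAMES.items():
        lines.append(f'2 {tag} "{name}"')
    lines += ["$EndPhysicalNames", "$Nodes", str(mesh.n_vertices)]
    for i, v in enumerate(mesh.vertices, start=1):
        lines.append(f"{i} {float(v[0])!r} {float(v[1])!r} {float(v[2])!r}")
    lines += ["$EndNodes", "$Elements", str(len(mesh.facets) + len(mesh.cells))]
    eid = 1
    for f, t in zip(mesh.facets, mesh.facet_tags):
        lines.append(f"{eid} {_MSH_TRI} 2 {t} {t} {f[0]+1} {f[1]+1} {f[2]+1}")
        eid += 1
    for c in mesh.cells:
        lines.append(f"{eid} {_MSH_TET} 2 0 0 {c[0]+1} {c[1]+1} {c[2]+1} {c[3]+1}")
        eid += 1
    lines.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_mesh(path) -> Mesh:
    """Read a labeled tet mesh from Gmsh MSH 2.2 ASCII."""
    with open(path) as fh:
        txt = fh.read().split("\n")
    try:
        i_fmt = txt.index("$MeshFormat")
    except ValueError as exc:
        raise MeshIOError(f"{path}: not a Gmsh MSH file") from exc
    if not txt[i_fmt + 1].startswith("2.2"):
        raise MeshIOError(f"{path}: unsupported MSH version {txt[i_fmt + 1]!r}")
    i_nodes = txt.index("$Nodes")
    n_nodes = int(txt[i_nodes + 1])
    verts = np.empty((n_nodes, 3))
    for row in range(n_nodes):
        parts = txt[i_nodes + 2 + row].split()
        verts[int(parts[0]) - 1] = [float(p) for p in parts[1:4]]
    i_el = txt.index("$Elements")
    n_el = int(txt[i_el + 1])
    facets, tags, cells = [], [], []
    for row in range(n_el):
        parts = txt[i_el + 2 + row].split()
        etype, ntags = int(parts[1]), int(parts[2])
        conn = [int(p) - 1 for p in parts[3 + ntags:]]
        if etype == _MSH_TRI:
            facets.append(conn)
            tags.append(int(parts[3]) if ntags else 0)
        elif etype == _MSH_TET:
            cells.append(conn)
    if not cells:
        raise MeshIOError(f"{path}: no tetrahedra found")
    if not facets or any(t not in FACET_TAG_NAMES for t in tags):
        raise MeshIOError(
            f"{path}: missing or invalid facet_labels (boundary triangles must "
            "carry physical tags endo=1, epi=2, base=3)"
        )
    return Mesh(
        vertices=verts,
        cells=np.asarray(cells, np.int64),
        facets=np.asarray(facets, np.int64),
        facet_tags=np.asarray(tags, int),
    )
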