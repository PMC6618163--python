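"""Passive inflation of the ventricle: Guccione hyperelasticity, P1 finite
elements, incremental follower-pressure loading and Newton's method.

Constitutive model (transversely isotropic, nearly incompressible):

    Psi(E) = C/2 (exp(W) - 1) + K (J ln J - J + 1)
    W = b_ff E_ff^2 + b_xx (E_ss^2 + E_nn^2 + E_sn^2 + E_ns^2)
              + b_fx (E_fn^2 + E_nf^2 + E_fs^2 + E_sf^2)

with E the Green-Lagrange strain expressed in the local fiber (f), sheet
(s) and sheet-normal (n) axes, J = det F, C and K in kPa. The second
Piola-Kirchhoff stress is S = dPsi/dE, derived analytically below.

Boundary conditions: follower pressure (normal to the deformed surface) on
the endocardium, traction-free epicardium, and at the base zero
longitudinal displacement plus linear in-plane springs (Robin condition).
Displacements solve -div(F S) = 0 in the reference domain, discretized
with continuous piecewise-linear vector fields and one-point quadrature
(F is constant per tetrahedron), assembled deterministically.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._fem import cell_volumes_and_gradients, lumped_facet_vertex_areas
from .fibers import FiberFrameField
from .geometry import BASE, ENDO, Mesh


class NonPhysicalStateError(RuntimeError):
    """The deformation state is inadmissible (J <= 0 somewhere)."""


class NonConvergenceError(RuntimeError):
    """Newton iteration failed to converge at some load step."""

    def __init__(self, step: int, pressure: float, residual: float):
        self.step, self.pressure, self.residual = step, pressure, residual
        super().__init__(
            f"Newton diverged at load step {step} (p={pressure:.4g} kPa, "
            f"residual {residual:.3e})"
        )


@dataclass(frozen=True)
class GuccioneParameters:
    """Material parameters; defaults are the study's mean values."""

    C: float = 1.1       # kPa, multiplicative factor
    b_ff: float = 6.6    # fiber stiffness exponent
    b_xx: float = 4.0    # cross-fiber stiffness exponent
    b_fx: float = 2.6    # fiber shear exponent
    K: float = 10.0      # kPa, incompressibility penalty factor

    def __post_init__(self):
        for name in ("C", "b_ff", "b_xx", "b_fx", "K"):
            if getattr(self, name) <= 0:
                raise ValueError(f"material parameter {name} must be positive")

    @property
    def exponent_matrix(self) -> np.ndarray:
        """Quadratic-form coefficients of W in fiber coordinates."""
        return np.array(
            [
                [self.b_ff, self.b_fx, self.b_fx],
                [self.b_fx, self.b_xx, self.b_xx],
                [self.b_fx, self.b_xx, self.b_xx],
            ]
        )


@dataclass
class DeformationState:
    """Pointwise kinematic state: F, E = (F^T F - I)/2, J = det F."""

    F: np.ndarray
    E: np.ndarray
    J: float

    @classmethod
    def from_F(cls, F: np.ndarray) -> "DeformationState":
        F = np.asarray(F, float)
        E = 0.5 * (F.T @ F - np.eye(3))
        J = float(np.linalg.det(F))
        if J <= 0:
            raise NonPhysicalStateError(f"det F = {J:.3g} <= 0")
        return cls(F=F, E=E, J=J)

    def validate(self) -> None:
        if np.abs(self.E - 0.5 * (self.F.T @ self.F - np.eye(3))).max() > 1e-12:
            raise ValueError("E inconsistent with F")
        if self.J <= 0:
            raise NonPhysicalStateError(f"det F = {self.J:.3g} <= 0")


@dataclass(frozen=True)
class BoundaryConditionConfig:
    endo_pressure: float = 2.0     # kPa
    base_spring: float = 1.0       # kPa/cm, in-plane Robin stiffness
    n_load_steps: int = 10
    newton_rel_tol: float = 1e-8
    newton_max_iter: int = 25
    #: reuse the factorized tangent while the residual contracts fast enough
    #: (chord iterations); set False for textbook full Newton steps
    reuse_tangent: bool = True

    def __post_init__(self):
        if self.endo_pressure < 0:
            raise ValueError("endo_pressure must be >= 0")
        if self.n_load_steps < 1:
            raise ValueError("n_load_steps must be >= 1")


@dataclass
class DisplacementField:
    """Nodal displacement vectors (cm)."""

    u: np.ndarray

    def validate(self, mesh: Mesh) -> None:
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement contains non-finite entries")
        base = mesh.vertices_of(BASE)
        if np.abs(self.u[base, 2]).max() > 1e-10:
            raise ValueError("longitudinal displacement nonzero on the base")


# ---------------------------------------------------------------------------
# constitutive law (batched over quadrature points)
# ---------------------------------------------------------------------------

def _det3(A: np.ndarray) -> np.ndarray:
    """Batched 3x3 determinant (faster than np.linalg.det for many cells)."""
    return (
        A[..., 0, 0] * (A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1])
        - A[..., 0, 1] * (A[..., 1, 0] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 0])
        + A[..., 0, 2] * (A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0])
    )


def _inv3(A: np.ndarray, det: np.ndarray) -> np.ndarray:
    """Batched 3x3 inverse via the adjugate."""
    out = np.empty_like(A)
    out[..., 0, 0] = A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1]
    out[..., 0, 1] = A[..., 0, 2] * A[..., 2, 1] - A[..., 0, 1] * A[..., 2, 2]
    out[..., 0, 2] = A[..., 0, 1] * A[..., 1, 2] - A[..., 0, 2] * A[..., 1, 1]
    out[..., 1, 0] = A[..., 1, 2] * A[..., 2, 0] - A[..., 1, 0] * A[..., 2, 2]
    out[..., 1, 1] = A[..., 0, 0] * A[..., 2, 2] - A[..., 0, 2] * A[..., 2, 0]
    out[..., 1, 2] = A[..., 0, 2] * A[..., 1, 0] - A[..., 0, 0] * A[..., 1, 2]
    out[..., 2, 0] = A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]
    out[..., 2, 1] = A[..., 0, 1] * A[..., 2, 0] - A[..., 0, 0] * A[..., 2, 1]
    out[..., 2, 2] = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    return out / det[..., None, None]


def _kinematics(F: np.ndarray):
    C_ = np.einsum("...ki,...kj->...ij", F, F)
    E = 0.5 * (C_ - np.eye(3))
    J = _det3(F)
    return C_, E, J


def _energy_batch(F, R, B, Cmat, K):
    """Strain energy density per point. F,R: (...,3,3); B: (3,3)."""
    _, E, J = _kinematics(F)
    if np.any(J <= 0):
        raise NonPhysicalStateError("det F <= 0 at a quadrature point")
    Et = np.einsum("...ia,...ij,...jb->...ab", R, E, R)
    W = np.einsum("ab,...ab,...ab->...", B, Et, Et)
    return 0.5 * Cmat * (np.exp(W) - 1.0) + K * (J * np.log(J) - J + 1.0)


def _second_w_derivative(R: np.ndarray, B: np.ndarray) -> np.ndarray:
    """d^2 W / dE^2 in global coordinates; independent of the strain."""
    return 2.0 * np.einsum("ab,...ma,...jb,...pa,...qb->...mjpq", B, R, R, R, R,
                           optimize=True)


def _stress_batch(F, R, B, Cmat, K, with_tangent: bool, d2W=None):
    """Second PK stress S and first PK stress P = F S; optionally the
    material tangent A_iJkL = dP_iJ / dF_kL."""
    C_, E, J = _kinematics(F)
    if np.any(J <= 0):
        raise NonPhysicalStateError("det F <= 0 at a quadrature point")
    Ci = _inv3(C_, J * J)
    Et = np.einsum("...ia,...ij,...jb->...ab", R, E, R, optimize=True)
    BEt = B * Et
    W = np.einsum("...ab,...ab->...", Et, BEt)
    # exp(W) may transiently overflow during line-search trial states; the
    # resulting inf residual is rejected by the backtracking logic
    with np.errstate(over="ignore", invalid="ignore"):
        expW = np.exp(W)[..., None, None]
    D = 2.0 * np.einsum("...ia,...ab,...jb->...ij", R, BEt, R, optimize=True)  # dW/dE
    lnJ = np.log(J)[..., None, None]
    Jn = J[..., None, None]
    S = 0.5 * Cmat * expW * D + K * lnJ * Jn * Ci
    P = np.einsum("...ij,...jk->...ik", F, S)
    if not with_tangent:
        return S, P, None
    if d2W is None:
        d2W = _second_w_derivative(R, B)
    dSdev = 0.5 * Cmat * expW[..., None, None] * (
        np.einsum("...mj,...pq->...mjpq", D, D) + d2W
    )
    CiCi = np.einsum("...mj,...pq->...mjpq", Ci, Ci)
    CiXCi = np.einsum("...mp,...qj->...mjpq", Ci, Ci) + np.einsum(
        "...mq,...pj->...mjpq", Ci, Ci
    )
    # d(C^-1)_MJ/dE_PQ = -(Ci_MP Ci_QJ + Ci_MQ Ci_PJ) under dC = 2 dE
    dSvol = K * (
        (lnJ[..., None, None] + 1.0) * Jn[..., None, None] * CiCi
        - lnJ[..., None, None] * Jn[..., None, None] * CiXCi
    )
    dSdE = dSdev + dSvol
    # A_iJkL = delta_ik S_JL + F_iM dS_MJ/dE_PQ * 1/2(d_PL F_kQ + F_kP d_QL)
    FdS = np.einsum("...im,...mjpq->...ijpq", F, dSdE, optimize=True)
    A = 0.5 * (
        np.einsum("...ijlq,...kq->...ijkl", FdS, F, optimize=True)
        + np.einsum("...ijpl,...kp->...ijkl", FdS, F, optimize=True)
    )
    eye = np.eye(3)
    A = A + np.einsum("ik,...jl->...ijkl", eye, S)
    return S, P, A


def strain_energy(
    state: DeformationState, frame: np.ndarray, params: GuccioneParameters
) -> float:
    """Strain energy density (kPa) at a single material point.

    ``frame`` is a 3x3 matrix with columns (f, s, n).
    """
    state.validate()
    return float(
        _energy_batch(state.F, np.asarray(frame, float), params.exponent_matrix,
                      params.C, params.K)
    )


def second_pk_stress(
    state: DeformationState, frame: np.ndarray, params: GuccioneParameters
) -> np.ndarray:
    """Second Piola-Kirchhoff stress S = dPsi/dE (kPa), symmetric."""
    state.validate()
    S, _, _ = _stress_batch(
        state.F, np.asarray(frame, float), params.exponent_matrix,
        params.C, params.K, with_tangent=False
    )
    S = 0.5 * (S + np.swapaxes(S, -1, -2))
    return S


# ---------------------------------------------------------------------------
# nonlinear solver
# ---------------------------------------------------------------------------

def _element_frames(mesh: Mesh, frame: FiberFrameField) -> np.ndarray:
    """Cell-center triads: vertex triads averaged and re-orthonormalized."""
    f = frame.f[mesh.cells].mean(axis=1)
    s = frame.s[mesh.cells].mean(axis=1)
    f /= np.linalg.norm(f, axis=1)[:, None]
    s -= f * np.einsum("ij,ij->i", s, f)[:, None]
    s /= np.linalg.norm(s, axis=1)[:, None]
    n = np.cross(f, s)
    return np.stack([f, s, n], axis=-1)


class _Assembler:
    """Precomputed structures for repeated residual/tangent assembly."""

    def __init__(self, mesh: Mesh, frame: FiberFrameField, params: GuccioneParameters,
                 bc: BoundaryConditionConfig):
        self.mesh, self.params, self.bc = mesh, params, bc
        self.vol, self.grads = cell_volumes_and_gradients(mesh.vertices, mesh.cells)
        self.R = _element_frames(mesh, frame)
        self.B = params.exponent_matrix
        self._d2W = _second_w_derivative(self.R, self.B)
        self._scale_cache: dict[float, float] = {}
        n = mesh.n_vertices
        self.ndof = 3 * n

        # constrained dofs: z on base vertices
        base_v = mesh.vertices_of(BASE)
        fixed = np.zeros(self.ndof, bool)
        fixed[3 * base_v + 2] = True
        self.free = ~fixed
        self.reduced_index = -np.ones(self.ndof, np.int64)
        self.reduced_index[self.free] = np.arange(self.free.sum())

        # volume-term sparsity (12x12 blocks per cell)
        cdof = (3 * mesh.cells[:, :, None] + np.arange(3)).reshape(-1, 12)
        self.cell_dofs = cdof
        vol_rows = np.repeat(cdof, 12, axis=1).ravel()
        vol_cols = np.tile(cdof, (1, 12)).ravel()

        # base springs (lumped in-plane)
        areas = lumped_facet_vertex_areas(n, mesh.vertices, mesh.facets_of(BASE))
        self.spring_dofs = np.concatenate([3 * base_v, 3 * base_v + 1])
        self.spring_k = bc.base_spring * np.concatenate([areas[base_v], areas[base_v]])

        # endocardial facets for the follower pressure
        self.endo = mesh.facets_of(ENDO)
        edof = (3 * self.endo[:, :, None] + np.arange(3)).reshape(-1, 9)
        press_rows = np.repeat(edof, 9, axis=1).ravel()
        press_cols = np.tile(edof, (1, 9)).ravel()
        self.endo_dofs = edof

        self.nfree = int(self.free.sum())

        # one fixed CSC sparsity pattern for all three contributions, so
        # repeated assemblies are a bincount, not a sort
        rows = np.concatenate([vol_rows, self.spring_dofs, press_rows])
        cols = np.concatenate([vol_cols, self.spring_dofs, press_cols])
        keep = self.free[rows] & self.free[cols]
        self._keep = keep
        self._n_vol = len(vol_rows)
        self._n_spring = len(self.spring_dofs)
        r = self.reduced_index[rows[keep]]
        c = self.reduced_index[cols[keep]]
        lin = c.astype(np.int64) * self.nfree + r
        uniq, slot = np.unique(lin, return_inverse=True)
        self._slot = slot
        self._nnz = len(uniq)
        self._csc_indices = (uniq % self.nfree).astype(np.int32)
        cols_of = uniq // self.nfree
        self._csc_indptr = np.searchsorted(
            cols_of, np.arange(self.nfree + 1)
        ).astype(np.int32)

    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        u = u.reshape(-1, 3)
        return np.eye(3) + np.einsum("eai,eaj->eji", self.grads, u[self.mesh.cells])

    def internal(self, u, with_tangent):
        F = self.deformation_gradients(u)
        _, P, A = _stress_batch(F, self.R, self.B, self.params.C, self.params.K,
                                with_tangent, d2W=self._d2W)
        fe = np.einsum("e,eij,eaj->eai", self.vol, P, self.grads, optimize=True)
        r = np.zeros(self.ndof)
        np.add.at(r, self.cell_dofs.ravel(), fe.reshape(-1, 12).ravel())
        vals = None
        if with_tangent:
            ke = np.einsum("e,eijkl,eaj,ebl->eaibk", self.vol, A, self.grads,
                           self.grads, optimize=True)
            vals = ke.reshape(len(self.vol), 12, 12)
        return r, vals

    def pressure(self, u, p, with_tangent):
        """Consistent follower-pressure nodal forces on the endocardium.

        Facets are outward-oriented for the solid, so the traction -p n
        gives nodal forces -(p/6) (x2-x1) x (x3-x1) in deformed coordinates.
        """
        x = (self.mesh.vertices + u.reshape(-1, 3))[self.endo]
        e1, e2 = x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]
        g = np.cross(e1, e2)
        f_node = -(p / 6.0) * g
        r = np.zeros(self.ndof)
        fe = np.repeat(f_node[:, None, :], 3, axis=1)
        np.add.at(r, self.endo_dofs.ravel(), fe.reshape(-1, 9).ravel())
        vals = None
        if with_tangent:
            # d f_r / d x_c = -(p/6) skew(edge_c), edge_c opposite-edge vectors
            ecs = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]],
                           axis=1)  # (nf, 3 cols, 3)
            sk = np.zeros(ecs.shape[:2] + (3, 3))
            a, b, c = ecs[..., 0], ecs[..., 1], ecs[..., 2]
            sk[..., 0, 1], sk[..., 0, 2] = -c, b
            sk[..., 1, 0], sk[..., 1, 2] = c, -a
            sk[..., 2, 0], sk[..., 2, 1] = -b, a
            blocks = -(p / 6.0) * sk  # (nf, col, 3, 3)
            vals = np.tile(blocks[:, None], (1, 3, 1, 1, 1))  # rows r = 0..2
            vals = np.transpose(vals, (0, 1, 3, 2, 4)).reshape(-1, 9, 9)
        return r, vals

    def residual(self, u, p):
        r_int, _ = self.internal(u, False)
        r_pr, _ = self.pressure(u, p, False)
        r = r_int - r_pr
        r[self.spring_dofs] += self.spring_k * u.ravel()[self.spring_dofs]
        return r[self.free]

    def tangent_and_residual(self, u, p):
        r_int, kv = self.internal(u, True)
        r_pr, kp = self.pressure(u, p, True)
        r = r_int - r_pr
        r[self.spring_dofs] += self.spring_k * u.ravel()[self.spring_dofs]

        data = np.concatenate([kv.reshape(-1), self.spring_k, -kp.reshape(-1)])
        datac = np.bincount(self._slot, weights=data[self._keep],
                            minlength=self._nnz)
        Kred = sp.csc_matrix(
            (datac, self._csc_indices, self._csc_indptr),
            shape=(self.nfree, self.nfree),
        )
        return Kred, r[self.free]

    def external_scale(self, p) -> float:
        if p not in self._scale_cache:
            r_pr, _ = self.pressure(np.zeros((self.mesh.n_vertices, 3)), p, False)
            self._scale_cache[p] = float(np.linalg.norm(r_pr))
        return self._scale_cache[p]


def solve_passive_inflation(
    mesh: Mesh,
    frame: FiberFrameField,
    params: GuccioneParameters = GuccioneParameters(),
    bc: BoundaryConditionConfig = BoundaryConditionConfig(),
    return_info: bool = False,
):
    """Quasi-static inflation to ``bc.endo_pressure`` by incremental loading.

    Returns the converged :class:`DisplacementField`; with
    ``return_info=True`` also a dict holding the per-step Newton residual
    histories. Raises :class:`NonConvergenceError` if Newton stalls at any
    load step and :class:`NonPhysicalStateError` if an element inverts.
    """
    asm = _Assembler(mesh, frame, params, bc)
    n = mesh.n_vertices
    u = np.zeros((n, 3))
    u_prev = np.zeros_like(u)

    ref_scale = asm.external_scale(max(bc.endo_pressure, 1e-12))
    atol = 1e-10 * max(ref_scale, 1.0)

    pressures = bc.endo_pressure * np.arange(1, bc.n_load_steps + 1) / bc.n_load_steps
    if bc.endo_pressure == 0.0:
        pressures = np.array([0.0])

    lu, refactor = None, True
    histories: list[list[float]] = []
    for step, p in enumerate(pressures, start=1):
        # secant predictor from the previous two converged steps
        if step > 2:
            u, u_prev = 2 * u - u_prev, u.copy()
        elif step == 2:
            u_prev = u.copy()

        converged = False
        tol_step = bc.newton_rel_tol * max(asm.external_scale(p), atol) + atol
        rfree = asm.residual(u.reshape(-1), p)
        fresh = False
        hist: list[float] = []
        for it in range(bc.newton_max_iter):
            rnorm = np.linalg.norm(rfree)
            hist.append(float(rnorm))
            if rnorm <= tol_step:
                converged = True
                break
            if lu is None or not bc.reuse_tangent or refactor:
                Kred, rfree = asm.tangent_and_residual(u.reshape(-1), p)
                lu = spla.splu(Kred, permc_spec="MMD_AT_PLUS_A")
                fresh, refactor = True, False
            du = lu.solve(-rfree)
            # damped update: backtrack on element inversion or residual growth
            alpha = 1.0
            unew = None
            for _ in range(6):
                cand = u.reshape(-1).copy()
                cand[asm.free] += alpha * du
                try:
                    with np.errstate(over="ignore", invalid="ignore"):
                        rcand = asm.residual(cand, p)
                        rn = np.linalg.norm(rcand)
                    if np.isnan(rn):
                        rn = np.inf
                except NonPhysicalStateError:
                    rn = np.inf
                if np.isfinite(rn) and (rn < rnorm or (alpha < 0.2 and fresh)):
                    unew = cand
                    break
                alpha *= 0.5
            if unew is None:
                if fresh:
                    break
                refactor = True       # stale tangent: rebuild and retry
                continue
            u = unew.reshape(n, 3)
            rfree = rcand
            # chord contraction too slow: refresh the tangent next iteration
            if rn > 0.2 * rnorm and not fresh:
                refactor = True
            fresh = False
        if not converged:
            # re-evaluate once more: the last quadratic step may land converged
            rfinal = np.linalg.norm(asm.residual(u.reshape(-1), p))
            if rfinal > tol_step:
                raise NonConvergenceError(step, p, rfinal)
        histories.append(hist)

    disp = DisplacementField(u=u)
    disp.validate(mesh)
    if return_info:
        return disp, {"pressures": pressures, "residual_histories": histories}
    return disp
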