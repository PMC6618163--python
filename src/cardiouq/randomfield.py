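"""Karhunen-Loeve representation of Gaussian fiber-angle noise.

A zero-mean Gaussian random field F(x) with squared-exponential covariance

    C(x, y) = sigma_KL^2 exp(-|x - y|^2 / (2 l^2))

is discretized on the mesh vertices through the Galerkin generalized
eigenproblem T phi_k = lambda_k M phi_k with T = M Q M, M the P1 mass
matrix and Q_ij = C(x_i, x_j). Truncating at n_KL modes gives the
parametric representation F(x) = sum_k eta_k sqrt(lambda_k) phi_k(x) with
independent standard-normal eta_k. Samples of F, in radians, rigidly
rotate the local (fiber, sheet) pair about the sheet-normal axis.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._fem import assemble_mass
from .fibers import FiberFrameField
from .geometry import Mesh


class CapacityError(RuntimeError):
    """Dense covariance assembly refused for an oversized mesh."""


class TruncationError(RuntimeError):
    """The error-variance criterion cannot be met with the available modes."""


@dataclass(frozen=True)
class CovarianceModel:
    """Squared-exponential covariance of the fiber-angle field."""

    sigma_kl: float = 0.1   # field standard deviation, radians
    l: float = 5.0          # correlation length, cm

    def __post_init__(self):
        if self.sigma_kl <= 0 or self.l <= 0:
            raise ValueError("sigma_kl and l must be positive")

    def kernel(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        d2 = ((x[:, None, :] - y[None, :, :]) ** 2).sum(-1)
        return self.sigma_kl**2 * np.exp(-d2 / (2 * self.l**2))


@dataclass
class DiscreteOperators:
    M: sp.csr_matrix     # P1 mass matrix, SPD
    Q: np.ndarray        # dense covariance matrix, PSD
    cov: CovarianceModel

    @property
    def T(self) -> np.ndarray:
        """T = M Q M, formed explicitly (desk-scale meshes)."""
        Md = self.M.toarray() if sp.issparse(self.M) else self.M
        return Md @ self.Q @ Md


@dataclass
class KLEBasis:
    """Leading eigenpairs of the covariance operator, M-orthonormal modes."""

    eigenvalues: np.ndarray   # (k,), descending, >= 0
    modes: np.ndarray         # (n, k), phi_j^T M phi_k = delta_jk
    cov: CovarianceModel
    n_kl: int | None = None   # truncation order set by truncate_by_error_variance

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def truncated(self, n_kl: int) -> "KLEBasis":
        return KLEBasis(
            eigenvalues=self.eigenvalues[:n_kl],
            modes=self.modes[:, :n_kl],
            cov=self.cov,
            n_kl=n_kl,
        )


@dataclass
class FieldSample:
    """One realization: standard-normal coordinates and nodal values (rad)."""

    eta: np.ndarray
    values: np.ndarray


def assemble_operators(
    mesh: Mesh, cov: CovarianceModel, node_cap: int = 20_000
) -> DiscreteOperators:
    """Mass matrix and dense nodal covariance matrix for the mesh."""
    n = mesh.n_vertices
    if n > node_cap:
        raise CapacityError(
            f"dense covariance for {n} nodes exceeds the cap ({node_cap}); "
            "coarsen the mesh or raise node_cap"
        )
    M = assemble_mass(mesh.vertices, mesh.cells)
    Q = cov.kernel(mesh.vertices, mesh.vertices)
    return DiscreteOperators(M=M, Q=Q, cov=cov)


def solve_kle(ops: DiscreteOperators, n_request: int) -> KLEBasis:
    """Leading eigenpairs of T phi = lambda M phi, M-orthonormal.

    Small problems use a dense symmetric solve; larger ones an implicitly
    restarted Lanczos iteration on the matrix-product operator. Mode signs
    are fixed by making the largest-magnitude entry positive.
    """
    n = ops.M.shape[0]
    if not 1 <= n_request <= n - 1:
        raise ValueError(f"n_request must be in [1, {n - 1}]")
    Md = ops.M.toarray()
    if n <= 1500:
        T = Md @ ops.Q @ Md
        T = 0.5 * (T + T.T)
        w, v = scipy.linalg.eigh(
            T, Md, subset_by_index=(n - n_request, n - 1)
        )
        w, v = w[::-1], v[:, ::-1]
    else:
        Mcsr = ops.M.tocsr()
        lu = spla.splu(ops.M.tocsc())

        def matvec(x):
            return Mcsr @ (ops.Q @ (Mcsr @ x))

        T_op = spla.LinearOperator((n, n), matvec=matvec, dtype=float)
        Minv = spla.LinearOperator((n, n), matvec=lu.solve, dtype=float)
        w, v = spla.eigsh(T_op, k=n_request, M=ops.M, Minv=Minv, which="LM")
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
    # normalize (eigh already M-orthonormalizes; enforce exactly) and fix signs
    mn = np.einsum("ik,ij,jk->k", v, Md, v)
    v = v / np.sqrt(mn)
    idx = np.abs(v).argmax(axis=0)
    signs = np.sign(v[idx, np.arange(v.shape[1])])
    v = v * signs
    return KLEBasis(eigenvalues=w, modes=v, cov=ops.cov)


def error_variance(basis: KLEBasis, n: int) -> np.ndarray:
    """Normalized pointwise truncation error variance at each vertex.

    err(x) = 1 - sum_{k<=n} lambda_k phi_k(x)^2 / C(x, x), with
    C(x, x) = sigma_KL^2 for the stationary kernel used here.
    """
    lam, phi = basis.eigenvalues[:n], basis.modes[:, :n]
    captured = (lam[None, :] * phi**2).sum(axis=1)
    return 1.0 - captured / basis.cov.sigma_kl**2


def truncate_by_error_variance(
    basis: KLEBasis,
    cov: CovarianceModel | None = None,
    threshold: float = 0.05,
    fraction: float = 0.92,
) -> int:
    """Smallest n_KL with error variance below ``threshold`` at a
    ``fraction`` of vertices.

    The error variance is normalized by the pointwise field variance
    C(x, x) = sigma_KL^2, which makes the criterion independent of the
    field amplitude.
    """
    for n in range(1, basis.n_modes + 1):
        frac_ok = float(np.mean(error_variance(basis, n) < threshold))
        if frac_ok >= fraction:
            return n
    raise TruncationError(
        f"criterion (err < {threshold} at {fraction:.0%} of vertices) not met "
        f"with {basis.n_modes} modes; achieved fraction {frac_ok:.2%}"
    )


def sample_field(
    basis: KLEBasis,
    eta: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> FieldSample:
    """Realize the truncated field from given or freshly drawn eta."""
    n_kl = basis.n_kl or basis.n_modes
    if eta is None:
        if rng is None:
            raise ValueError("provide either eta or a seeded rng")
        eta = rng.standard_normal(n_kl)
    eta = np.asarray(eta, float)
    if eta.shape != (n_kl,):
        raise ValueError(f"eta has shape {eta.shape}, expected ({n_kl},)")
    lam, phi = basis.eigenvalues[:n_kl], basis.modes[:, :n_kl]
    values = phi @ (eta * np.sqrt(np.maximum(lam, 0.0)))
    return FieldSample(eta=eta, values=values)


def perturb_fiber_frame(frame: FiberFrameField, field: FieldSample) -> FiberFrameField:
    """Rotate the (f, s) pair about the sheet normal n by the sampled angle.

    A rigid rotation preserves orthonormality and handedness of the triad,
    which a literal vector addition to f would not.
    """
    theta = np.asarray(field.values, float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("field sample contains non-finite angles")
    c, s = np.cos(theta)[:, None], np.sin(theta)[:, None]
    f_new = c * frame.f + s * np.cross(frame.n, frame.f)
    s_new = c * frame.s + s * np.cross(frame.n, frame.s)
    out = FiberFrameField(f=f_new, s=s_new, n=frame.n.copy())
    return out
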