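"""Guccione constitutive law and the nonlinear inflation solver."""
import math

import numpy as np
import pytest

from cardiouq._fem import cell_volumes_and_gradients
from cardiouq.mechanics import (
    BoundaryConditionConfig,
    DeformationState,
    DisplacementField,
    GuccioneParameters,
    NonPhysicalStateError,
    _Assembler,
    second_pk_stress,
    solve_passive_inflation,
    strain_energy,
)


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def admissible_state(rng, scale=0.1):
    F = np.eye(3) + scale * rng.normal(size=(3, 3))
    if np.linalg.det(F) <= 0.1:
        F = np.eye(3) + 0.02 * rng.normal(size=(3, 3))
    return DeformationState.from_F(F)


class TestStrainEnergy:
    def test_zero_strain_zero_energy(self):
        st = DeformationState.from_F(np.eye(3))
        assert strain_energy(st, np.eye(3), GuccioneParameters()) == 0.0

    def test_uniaxial_fiber_strain_hand_value(self, rng):
        """E_ff = 0.1, all other fiber-frame strains zero, arbitrary frame."""
        R = random_rotation(rng)
        lam = math.sqrt(1.2)                 # gives E_ff = (lam^2 - 1)/2 = 0.1
        F = R @ np.diag([lam, 1, 1]) @ R.T
        st = DeformationState.from_F(F)
        p = GuccioneParameters()
        J = lam
        expected = 0.5 * p.C * (math.exp(p.b_ff * 0.1**2) - 1) + p.K * (
            J * math.log(J) - J + 1
        )
        assert strain_energy(st, R, p) == pytest.approx(expected, rel=1e-12)

    def test_sheet_normal_swap_symmetry(self, rng):
        st = admissible_state(rng)
        R = random_rotation(rng)
        p = GuccioneParameters()
        Rswap = R[:, [0, 2, 1]] * np.array([1, 1, -1])   # keep right-handed
        assert strain_energy(st, R, p) == pytest.approx(
            strain_energy(st, Rswap, p), rel=1e-12
        )

    def test_inverted_state_rejected(self):
        with pytest.raises(NonPhysicalStateError):
            DeformationState.from_F(np.diag([1.0, 1.0, -1.0]))


class TestSecondPKStress:
    def test_stress_free_reference(self):
        st = DeformationState.from_F(np.eye(3))
        S = second_pk_stress(st, np.eye(3), GuccioneParameters())
        assert np.abs(S).max() < 1e-14

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_finite_differences_of_energy(self, seed):
        rng = np.random.default_rng(seed)
        st = admissible_state(rng)
        R = random_rotation(rng)
        p = GuccioneParameters()
        S = second_pk_stress(st, R, p)
        assert np.abs(S - S.T).max() < 1e-10
        # dPsi = P : dF with P = F S, so check against FD in F
        P = st.F @ S
        h = 1e-6
        for i in range(3):
            for j in range(3):
                Fp, Fm = st.F.copy(), st.F.copy()
                Fp[i, j] += h
                Fm[i, j] -= h
                fd = (
                    strain_energy(DeformationState.from_F(Fp), R, p)
                    - strain_energy(DeformationState.from_F(Fm), R, p)
                ) / (2 * h)
                assert fd == pytest.approx(P[i, j], rel=1e-6, abs=1e-8)

    def test_isotropic_limit_frame_independent(self, rng):
        p = GuccioneParameters(b_ff=3.0, b_xx=3.0, b_fx=3.0)
        st = admissible_state(rng)
        S1 = second_pk_stress(st, np.eye(3), p)
        S2 = second_pk_stress(st, random_rotation(rng), p)
        assert np.abs(S1 - S2).max() < 1e-10


class TestAssembledTangent:
    def test_tangent_matches_residual_differences(self, coarse_mesh, coarse_frame):
        """Second-order Taylor check of the assembled Jacobian."""
        asm = _Assembler(coarse_mesh, coarse_frame, GuccioneParameters(),
                         BoundaryConditionConfig())
        rng = np.random.default_rng(7)
        n = coarse_mesh.n_vertices
        u0 = 0.01 * rng.normal(size=3 * n)
        du = rng.normal(size=3 * n)
        du[~asm.free] = 0.0
        p = 0.5
        K, r0 = asm.tangent_and_residual(u0, p)
        lin = K @ du[asm.free]
        errs = []
        for eps in (1e-3, 5e-4, 2.5e-4):
            r1 = asm.residual(u0 + eps * du, p)
            errs.append(np.linalg.norm(r1 - r0 - eps * lin) / eps**2)
        # remainder / eps^2 bounded => Jacobian exact (observed order 2)
        assert max(errs) / min(errs) < 1.5


@pytest.fixture(scope="module")
def coarse_solution(coarse_mesh, coarse_frame):
    return solve_passive_inflation(coarse_mesh, coarse_frame)


class TestPassiveInflation:
    def test_zero_pressure_zero_displacement(self, coarse_mesh, coarse_frame):
        bc = BoundaryConditionConfig(endo_pressure=0.0)
        d = solve_passive_inflation(coarse_mesh, coarse_frame, bc=bc)
        assert np.abs(d.u).max() == 0.0

    def test_cavity_volume_increases_with_pressure(self, coarse_mesh, coarse_frame):
        from cardiouq.qoi import cavity_volume

        vols = []
        for p in (0.5, 1.0, 2.0):
            bc = BoundaryConditionConfig(endo_pressure=p, n_load_steps=5)
            d = solve_passive_inflation(coarse_mesh, coarse_frame, bc=bc)
            vols.append(cavity_volume(coarse_mesh, d))
        assert vols[0] < vols[1] < vols[2]

    def test_halving_stiffness_doubles_linearized_response(self, coarse_mesh, coarse_frame):
        """In the linear regime (0.05 kPa) the volume change scales ~1/C."""
        from cardiouq.qoi import cavity_volume

        bc = BoundaryConditionConfig(endo_pressure=0.05, n_load_steps=1)
        u0 = DisplacementField(u=np.zeros((coarse_mesh.n_vertices, 3)))
        v_ref = cavity_volume(coarse_mesh, u0)
        dv = []
        for C in (1.1, 0.55):
            d = solve_passive_inflation(
                coarse_mesh, coarse_frame, GuccioneParameters(C=C), bc
            )
            dv.append(cavity_volume(coarse_mesh, d) - v_ref)
        assert 1.8 < dv[1] / dv[0] < 2.2

    def test_base_longitudinally_clamped(self, coarse_mesh, coarse_solution):
        coarse_solution.validate(coarse_mesh)

    def test_jacobian_positive_and_moderately_compressible(
        self, coarse_mesh, coarse_solution
    ):
        """At 2 kPa with K = 10 kPa the tissue deviates noticeably from
        incompressibility (weak penalty), but no element inverts."""
        vol, grads = cell_volumes_and_gradients(coarse_mesh.vertices, coarse_mesh.cells)
        F = np.eye(3) + np.einsum(
            "eai,eaj->eji", grads, coarse_solution.u[coarse_mesh.cells]
        )
        J = np.linalg.det(F)
        assert J.min() > 0.8 and J.max() < 1.3

    def test_newton_quadratic_convergence(self, coarse_mesh, coarse_frame):
        bc = BoundaryConditionConfig(reuse_tangent=False, n_load_steps=4)
        _, info = solve_passive_inflation(
            coarse_mesh, coarse_frame, bc=bc, return_info=True
        )
        hist = info["residual_histories"][-1]
        # near the solution the residual ratio sequence contracts
        # superlinearly: r_{k+1} <= c * r_k^2 scaled by the initial residual
        tail = np.array(hist[-3:])
        rates = tail[1:] / tail[:-1]
        assert rates[-1] < 0.05 * rates[0] or tail[-1] < 1e-10 * hist[0]

    def test_load_step_invariance(self, coarse_mesh, coarse_frame):
        from cardiouq.qoi import compute_qois

        q1 = compute_qois(
            coarse_mesh,
            solve_passive_inflation(
                coarse_mesh, coarse_frame,
                bc=BoundaryConditionConfig(n_load_steps=10),
            ),
        ).as_array()
        q2 = compute_qois(
            coarse_mesh,
            solve_passive_inflation(
                coarse_mesh, coarse_frame,
                bc=BoundaryConditionConfig(n_load_steps=20),
            ),
        ).as_array()
        assert np.abs(q2 / q1 - 1).max() < 0.005

    def test_deterministic_rerun_bit_identical(self, coarse_mesh, coarse_frame):
        d1 = solve_passive_inflation(coarse_mesh, coarse_frame)
        d2 = solve_passive_inflation(coarse_mesh, coarse_frame)
        assert np.array_equal(d1.u, d2.u)
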