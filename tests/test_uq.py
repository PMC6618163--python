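"""Polynomial chaos, Sobol indices and quasi-Monte Carlo primitives."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiouq.uq import (
    FittingError,
    InputSpec,
    build_pce_basis,
    build_random_vector,
    expected_terms,
    fit_point_collocation,
    halton_points,
    qmc_estimate,
    sobol_indices,
    surrogate_statistics,
    validation_rmse,
)


# -- independent oracle: radical-inverse Halton ------------------------------

def radical_inverse(i: int, base: int) -> float:
    out, f = 0.0, 1.0 / base
    while i > 0:
        out += (i % base) * f
        i //= base
        f /= base
    return out


class TestInputSpecs:
    def test_angle_cov_is_015(self):
        spec = InputSpec("alpha_endo", "normal", 50.0, 7.5)
        assert spec.cov == pytest.approx(0.15)

    def test_lognormal_moment_matching(self, rng):
        rv = build_random_vector([InputSpec("K", "lognormal", 10.0, 1.5)])
        xi = rng.standard_normal((10**6, 1))
        eta = rv.to_physical(xi)
        assert eta.mean() == pytest.approx(10.0, rel=0.005)
        assert eta.std() == pytest.approx(1.5, rel=0.01)
        # xi = 0 maps to the median exp(m) < mean
        med = rv.to_physical(np.zeros((1, 1)))[0, 0]
        assert med < 10.0
        s2 = math.log(1 + (1.5 / 10) ** 2)
        assert med == pytest.approx(math.exp(math.log(10) - s2 / 2), rel=1e-12)

    def test_transform_roundtrip(self, rng):
        rv = build_random_vector(
            [InputSpec("a", "normal", -3.0, 2.0), InputSpec("b", "lognormal", 5.0, 1.0)]
        )
        xi = rng.standard_normal((200, 2))
        back = rv.to_standard(rv.to_physical(xi))
        assert np.abs(back - xi).max() < 1e-12

    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            InputSpec("x", "uniform", 0.0, 1.0)

    def test_lognormal_needs_positive_mean(self):
        with pytest.raises(ValueError):
            InputSpec("x", "lognormal", -1.0, 1.0)


class TestHalton:
    def test_base2_hand_values(self):
        assert np.allclose(halton_points(1, 3).ravel(), [0.5, 0.25, 0.75])

    def test_first_point_2d(self):
        assert np.allclose(halton_points(2, 1)[0], [0.5, 1 / 3])

    @pytest.mark.parametrize("d", [1, 3, 6])
    def test_matches_radical_inverse_oracle(self, d):
        primes = [2, 3, 5, 7, 11, 13][:d]
        pts = halton_points(d, 40)
        ref = np.array(
            [[radical_inverse(i, b) for b in primes] for i in range(1, 41)]
        )
        assert np.abs(pts - ref).max() < 1e-14

    def test_unit_cube(self):
        pts = halton_points(9, 500)
        assert pts.min() >= 0.0 and pts.max() < 1.0


class TestPCEBasis:
    @pytest.mark.parametrize(
        "d,N,M", [(9, 2, 55), (1, 1, 2), (4, 2, 15), (16, 2, 153)]
    )
    def test_term_counts(self, d, N, M):
        assert build_pce_basis(d, N).M == M
        assert expected_terms(N, d) == M

    @pytest.mark.parametrize("d", [2, 3])
    def test_orthonormal_under_gaussian_quadrature(self, d):
        from numpy.polynomial.hermite_e import hermegauss

        x, w = hermegauss(10)
        w = w / np.sqrt(2 * np.pi)
        grids = np.meshgrid(*([x] * d), indexing="ij")
        W = np.ones_like(grids[0])
        for g in np.meshgrid(*([w] * d), indexing="ij"):
            W = W * g
        pts = np.stack([g.ravel() for g in grids], axis=1)
        basis = build_pce_basis(d, 3)
        Phi = basis.evaluate(pts)
        G = (Phi * W.ravel()[:, None]).T @ Phi
        assert np.abs(G - np.eye(basis.M)).max() < 1e-8


class TestPointCollocation:
    def test_single_basis_function_recovered(self, rng):
        basis = build_pce_basis(3, 2)
        pts = rng.standard_normal((2 * basis.M, 3))
        j = 7
        evals = basis.evaluate(pts)[:, j]
        model = fit_point_collocation(basis, pts, evals)
        expect = np.zeros(basis.M)
        expect[j] = 1.0
        assert np.abs(model.coefficients[:, 0] - expect).max() < 1e-10

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(coefs=st.lists(st.floats(-5, 5), min_size=6, max_size=6))
    def test_exact_on_quadratic_polynomials(self, coefs):
        """Order-2 PCE reproduces any degree-2 polynomial of the inputs."""
        a0, a1, a2, a11, a22, a12 = coefs
        rng = np.random.default_rng(42)
        basis = build_pce_basis(2, 2)
        pts = rng.standard_normal((2 * basis.M, 2))

        def f(x):
            return (
                a0 + a1 * x[:, 0] + a2 * x[:, 1]
                + a11 * x[:, 0] ** 2 + a22 * x[:, 1] ** 2
                + a12 * x[:, 0] * x[:, 1]
            )

        model = fit_point_collocation(basis, pts, f(pts))
        test = rng.standard_normal((64, 2))
        assert validation_rmse(model, test, f(test))[0] < 1e-8

    def test_rank_deficient_system_raises(self):
        basis = build_pce_basis(2, 2)
        pts = np.tile(np.array([[0.3, -0.4]]), (2 * basis.M, 1))
        with pytest.warns(UserWarning, match="conditioned"):
            with pytest.raises(FittingError):
                fit_point_collocation(basis, pts, np.ones(2 * basis.M))

    def test_underdetermined_raises(self, rng):
        basis = build_pce_basis(3, 2)
        with pytest.raises(FittingError, match="underdetermined"):
            fit_point_collocation(basis, rng.standard_normal((5, 3)), np.ones(5))


class TestSurrogateStatistics:
    def test_constant_surrogate_degenerate(self):
        basis = build_pce_basis(2, 1)
        pts = np.array([[0.0, 0], [1, 0], [0, 1]])
        model = fit_point_collocation(basis, pts, np.full(3, 4.2))
        stats = surrogate_statistics(model, n_mc=1000, seed=0)
        assert stats.sigma[0] == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(stats.skewness[0]) and np.isnan(stats.kurtosis[0])

    def test_linear_gaussian_prediction_interval(self, rng):
        basis = build_pce_basis(1, 1)
        pts = rng.standard_normal((8, 1))
        model = fit_point_collocation(basis, pts, 2.0 + 0.5 * pts[:, 0])
        stats = surrogate_statistics(model, n_mc=200_000, seed=1)
        assert stats.mu[0] == pytest.approx(2.0, abs=1e-10)
        assert stats.sigma[0] == pytest.approx(0.5, abs=1e-10)
        lo, hi = stats.pi95[0]
        assert lo == pytest.approx(2 - 1.96 * 0.5, rel=0.01)
        assert hi == pytest.approx(2 + 1.96 * 0.5, rel=0.01)

    def test_analytic_sigma_consistent_with_mc(self, rng):
        basis = build_pce_basis(3, 2)
        pts = rng.standard_normal((2 * basis.M, 3))
        y = np.sin(1 + pts.sum(axis=1)) + pts[:, 0] ** 2
        model = fit_point_collocation(basis, pts, y)
        stats = surrogate_statistics(model, n_mc=100_000, seed=2)
        xi = np.random.default_rng(3).standard_normal((100_000, 3))
        mc_sigma = model(xi)[:, 0].std()
        se = mc_sigma / np.sqrt(2 * (100_000 - 1))  # rough SE of an SD
        assert abs(stats.sigma[0] - mc_sigma) < 5 * se + 1e-3


class TestSobol:
    def test_additive_model_indices_sum_to_one(self, rng):
        basis = build_pce_basis(3, 2)
        pts = rng.standard_normal((3 * basis.M, 3))
        y = 1.0 + 2 * pts[:, 0] + pts[:, 1] ** 2 - 0.5 * pts[:, 2]
        model = fit_point_collocation(basis, pts, y)
        res = sobol_indices(model)
        assert np.abs(res.main - res.total).max() < 1e-10
        assert res.main.sum() == pytest.approx(1.0, abs=1e-10)

    def test_known_variance_split(self, rng):
        """Y = xi1 + xi2^2: V = 3, S1 = 1/3, S2 = 2/3."""
        basis = build_pce_basis(2, 2)
        pts = rng.standard_normal((20, 2))
        model = fit_point_collocation(basis, pts, pts[:, 0] + pts[:, 1] ** 2)
        res = sobol_indices(model)
        assert res.variance[0] == pytest.approx(3.0, rel=1e-10)
        assert res.main[0, 0] == pytest.approx(1 / 3, rel=1e-10)
        assert res.main[1, 0] == pytest.approx(2 / 3, rel=1e-10)

    def test_against_double_loop_monte_carlo(self, rng):
        """Coefficient-based indices vs brute-force conditional variance."""
        basis = build_pce_basis(3, 2)
        pts = rng.standard_normal((3 * basis.M, 3))
        y = (
            pts[:, 0] * pts[:, 1] + 0.8 * pts[:, 2] ** 2 + 1.5 * pts[:, 0] + 0.3
        )
        model = fit_point_collocation(basis, pts, y)
        res = sobol_indices(model)
        n_out, n_in = 8000, 1000
        mc = np.random.default_rng(5)
        V = model(mc.standard_normal((200_000, 3)))[:, 0].var()
        for i in range(3):
            xi_i = mc.standard_normal(n_out)
            cond_means = np.empty(n_out)
            for k in range(n_out):
                xi = mc.standard_normal((n_in, 3))
                xi[:, i] = xi_i[k]
                cond_means[k] = model(xi)[:, 0].mean()
            S_mc = cond_means.var() / V
            assert abs(S_mc - res.main[i, 0]) < 0.02

    def test_interactions_separate_main_from_total(self, rng):
        basis = build_pce_basis(2, 2)
        pts = rng.standard_normal((3 * basis.M, 2))
        y = pts[:, 0] * pts[:, 1]
        model = fit_point_collocation(basis, pts, y)
        res = sobol_indices(model)
        assert np.abs(res.main).max() < 1e-10
        assert res.total[0, 0] == pytest.approx(1.0, rel=1e-10)
        assert res.main.sum() <= 1.0 + 1e-6 <= res.total.sum() + 1e-6


class TestQMCEstimate:
    def test_linear_integrand_mean_error(self):
        """Mean error below 1e-3 sigma at n = 4096, decaying ~ 1/n
        (much faster than the n^-1/2 of plain Monte Carlo)."""
        rv = build_random_vector([InputSpec("x", "normal", 3.0, 2.0)])
        errs = {
            n: abs(qmc_estimate(lambda eta: np.array([eta[0]]), rv, n).mu[0] - 3.0)
            for n in (512, 4096)
        }
        assert errs[4096] < 1e-3 * 2.0
        assert errs[4096] < errs[512] / 4.0

    def test_deterministic_rerun(self):
        rv = build_random_vector([InputSpec("x", "normal", 0.0, 1.0)])
        f = lambda eta: np.array([eta[0] ** 2, np.sin(eta[0])])  # noqa: E731
        s1 = qmc_estimate(f, rv, 256)
        s2 = qmc_estimate(f, rv, 256)
        assert np.array_equal(s1.mu, s2.mu) and np.array_equal(s1.sigma, s2.sigma)

    def test_quadratic_sigma_close_to_closed_form(self):
        """For Y = xi^2 with xi ~ N(0,1): Var(Y) = 2."""
        rv = build_random_vector([InputSpec("x", "normal", 0.0, 1.0)])
        stats = qmc_estimate(lambda eta: np.array([eta[0] ** 2]), rv, 4096)
        assert stats.sigma[0] == pytest.approx(np.sqrt(2.0), rel=0.01)

    def test_failed_points_skipped(self, caplog):
        rv = build_random_vector([InputSpec("x", "normal", 0.0, 1.0)])

        def flaky(eta):
            if abs(eta[0]) > 1.5:
                raise RuntimeError("boom")
            return np.array([eta[0]])

        stats = qmc_estimate(flaky, rv, 200)
        assert 0 < stats.n_samples < 200
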