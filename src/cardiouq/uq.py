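"""Nonintrusive uncertainty propagation: Hermite polynomial chaos by point
collocation, analytic Sobol indices, and Halton quasi-Monte Carlo.

All surrogates are built in standardized normal coordinates xi: normal
inputs map as eta = mu + sigma xi, lognormal inputs through their
underlying normal, so the tensorized probabilists' Hermite basis is
exactly orthonormal under the joint input density. With an orthonormal
basis the surrogate mean is the leading coefficient, the variance is the
sum of squared remaining coefficients, and main/total Sobol indices are
exact sums of squared coefficients over multi-index subsets.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.stats import qmc

logger = logging.getLogger(__name__)


class FittingError(RuntimeError):
    """The collocation system is rank deficient."""


@dataclass(frozen=True)
class InputSpec:
    """One scalar random input: family, mean and standard deviation."""

    name: str
    family: str            # "normal" | "lognormal"
    mu: float
    sigma: float

    def __post_init__(self):
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.sigma <= 0:
            raise ValueError(f"{self.name}: sigma must be positive")
        if self.family == "lognormal" and self.mu <= 0:
            raise ValueError(f"{self.name}: lognormal requires mu > 0")

    @property
    def cov(self) -> float:
        return self.sigma / abs(self.mu)


@dataclass(frozen=True)
class RandomVector:
    """Ordered independent scalar inputs with standard-normal transforms."""

    specs: tuple[InputSpec, ...]

    @property
    def d(self) -> int:
        return len(self.specs)

    def _lognormal_params(self, spec: InputSpec) -> tuple[float, float]:
        s2 = math.log(1.0 + (spec.sigma / spec.mu) ** 2)
        m = math.log(spec.mu) - s2 / 2.0
        return m, math.sqrt(s2)

    def to_physical(self, xi: np.ndarray) -> np.ndarray:
        """Map standard-normal coordinates (n, d) to physical inputs."""
        xi = np.atleast_2d(xi)
        out = np.empty_like(xi)
        for j, spec in enumerate(self.specs):
            if spec.family == "normal":
                out[:, j] = spec.mu + spec.sigma * xi[:, j]
            else:
                m, s = self._lognormal_params(spec)
                out[:, j] = np.exp(m + s * xi[:, j])
        return out

    def to_standard(self, eta: np.ndarray) -> np.ndarray:
        """Inverse transform: physical inputs back to standard normals."""
        eta = np.atleast_2d(eta)
        out = np.empty_like(eta)
        for j, spec in enumerate(self.specs):
            if spec.family == "normal":
                out[:, j] = (eta[:, j] - spec.mu) / spec.sigma
            else:
                m, s = self._lognormal_params(spec)
                out[:, j] = (np.log(eta[:, j]) - m) / s
        return out


def build_random_vector(table: list[InputSpec]) -> RandomVector:
    return RandomVector(specs=tuple(table))


def halton_points(d: int, n: int) -> np.ndarray:
    """First n points of the unscrambled Halton sequence in [0,1)^d.

    Bases are the first d primes and the sequence starts at index 1, i.e.
    for d=1 the points are 1/2, 1/4, 3/4, ...
    """
    if d < 1 or n < 1:
        raise ValueError("d and n must be >= 1")
    sampler = qmc.Halton(d=d, scramble=False)
    return sampler.random(n + 1)[1:]    # scipy starts at index 0 (the origin)


def halton_standard_normal(d: int, n: int, skip: int = 0) -> np.ndarray:
    """Halton points (optionally skipping a leading block) mapped through
    the inverse standard-normal CDF per coordinate."""
    sampler = qmc.Halton(d=d, scramble=False)
    pts = sampler.random(n + skip + 1)[1 + skip:]
    return stats.norm.ppf(pts)


# ---------------------------------------------------------------------------
# Hermite PCE
# ---------------------------------------------------------------------------

def _multi_indices(d: int, order: int) -> np.ndarray:
    """All multi-indices with total degree <= order, graded lexicographic."""
    out = [np.zeros(d, int)]
    for deg in range(1, order + 1):
        level = []

        def rec(prefix, remaining, slots):
            if slots == 1:
                level.append(prefix + [remaining])
                return
            for v in range(remaining, -1, -1):
                rec(prefix + [v], remaining - v, slots - 1)

        rec([], deg, d)
        out.extend(np.array(lvl) for lvl in level)
    return np.vstack(out)


def _hermite_norm(x: np.ndarray, order: int) -> np.ndarray:
    """Orthonormal probabilists' Hermite polynomials He_n(x)/sqrt(n!)
    for n = 0..order, evaluated columnwise; x of any shape."""
    vals = np.empty((order + 1,) + x.shape)
    vals[0] = 1.0
    if order >= 1:
        vals[1] = x
    for n in range(1, order):
        vals[n + 1] = x * vals[n] - n * vals[n - 1]
    fac = np.array([math.sqrt(math.factorial(n)) for n in range(order + 1)])
    return vals / fac.reshape((-1,) + (1,) * x.ndim)


@dataclass
class PCEBasis:
    """Tensorized orthonormal Hermite basis of total degree <= N."""

    d: int
    N: int
    indices: np.ndarray = field(init=False)

    def __post_init__(self):
        self.indices = _multi_indices(self.d, self.N)

    @property
    def M(self) -> int:
        return len(self.indices)

    def evaluate(self, xi: np.ndarray) -> np.ndarray:
        """Design matrix Phi (n_points, M) at standardized points."""
        xi = np.atleast_2d(xi)
        H = _hermite_norm(xi, self.N)          # (N+1, n, d)
        cols = [np.prod(H[self.indices[i], :, range(self.d)], axis=0)
                for i in range(self.M)]
        return np.stack(cols, axis=1)


def build_pce_basis(rv: RandomVector | int, N: int) -> PCEBasis:
    """Hermite basis for a random vector (or an explicit dimension)."""
    d = rv if isinstance(rv, int) else rv.d
    if N < 1:
        raise ValueError("polynomial order N must be >= 1")
    return PCEBasis(d=d, N=N)


def expected_terms(N: int, d: int) -> int:
    """M = (N + d)! / (N! d!)."""
    return math.comb(N + d, d)


@dataclass
class SurrogateModel:
    """Fitted PCE surrogate: coefficients per output on an orthonormal basis."""

    basis: PCEBasis
    coefficients: np.ndarray       # (M, n_outputs)
    output_names: tuple[str, ...]
    n_samples: int
    condition_number: float

    @property
    def d(self) -> int:
        return self.basis.d

    def __call__(self, xi: np.ndarray) -> np.ndarray:
        return self.basis.evaluate(xi) @ self.coefficients

    def mean(self) -> np.ndarray:
        return self.coefficients[0].copy()

    def std(self) -> np.ndarray:
        return np.sqrt((self.coefficients[1:] ** 2).sum(axis=0))


def fit_point_collocation(
    basis: PCEBasis,
    points: np.ndarray,
    evals: np.ndarray,
    output_names: tuple[str, ...] | None = None,
) -> SurrogateModel:
    """Least-squares point collocation (exact solve when N_s = M).

    ``points`` are standardized samples (N_s, d); ``evals`` the forward
    model outputs (N_s, n_outputs). Warns when the collocation matrix
    condition number exceeds 1e8.
    """
    points = np.atleast_2d(points)
    evals = np.asarray(evals, float)
    if evals.ndim == 1:
        evals = evals[:, None]
    if len(points) != len(evals):
        raise ValueError("points and evals must have equal length")
    if len(points) < basis.M:
        raise FittingError(
            f"underdetermined collocation: {len(points)} points for "
            f"{basis.M} coefficients"
        )
    Phi = basis.evaluate(points)
    cond = float(np.linalg.cond(Phi))
    if cond > 1e8:
        warnings.warn(
            f"collocation matrix poorly conditioned (cond={cond:.3g}); "
            "consider more or better-spread points",
            stacklevel=2,
        )
    coef, _, rank, _ = np.linalg.lstsq(Phi, evals, rcond=None)
    if rank < basis.M:
        raise FittingError(
            f"rank-deficient collocation system (rank {rank} < {basis.M}); "
            "add collocation points"
        )
    names = output_names or tuple(f"y{k}" for k in range(evals.shape[1]))
    return SurrogateModel(
        basis=basis, coefficients=coef, output_names=tuple(names),
        n_samples=len(points), condition_number=cond,
    )


def validation_rmse(model: SurrogateModel, points: np.ndarray,
                    evals: np.ndarray) -> np.ndarray:
    """Root mean-square error against held-out forward evaluations."""
    evals = np.asarray(evals, float)
    if evals.ndim == 1:
        evals = evals[:, None]
    pred = model(points)
    return np.sqrt(((pred - evals) ** 2).mean(axis=0))


# ---------------------------------------------------------------------------
# statistics and sensitivity
# ---------------------------------------------------------------------------

@dataclass
class StatSummary:
    """Distributional summary per output quantity."""

    names: tuple[str, ...]
    mu: np.ndarray
    sigma: np.ndarray
    pi95: np.ndarray            # (n_outputs, 2) central 95% interval
    skewness: np.ndarray
    kurtosis: np.ndarray        # excess kurtosis
    n_samples: int

    @property
    def cov(self) -> np.ndarray:
        return self.sigma / np.abs(self.mu)

    def normality_flags(self, bound: float = 1.96) -> np.ndarray:
        """True where both |skewness| and |excess kurtosis| fall within the
        normality screening band."""
        return (np.abs(self.skewness) <= bound) & (np.abs(self.kurtosis) <= bound)


def surrogate_statistics(
    model: SurrogateModel, n_mc: int = 100_000, seed: int | np.random.Generator = 0
) -> StatSummary:
    """Moments of the surrogate outputs.

    Mean and standard deviation are analytic in the coefficients; the
    prediction interval, skewness and kurtosis come from seeded Monte Carlo
    on the surrogate.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mu, sigma = model.mean(), model.std()
    xi = rng.standard_normal((n_mc, model.d))
    y = model(xi)
    pi95 = np.percentile(y, [2.5, 97.5], axis=0).T
    # constant outputs make the sample moments meaningless; computed anyway
    # and replaced by NaN below, so suppress the precision-loss warnings
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = stats.skew(y, axis=0)
        kurt = stats.kurtosis(y, axis=0)
    degenerate = sigma <= 1e-14 * np.maximum(np.abs(mu), 1.0)
    skew = np.where(degenerate, np.nan, skew)
    kurt = np.where(degenerate, np.nan, kurt)
    return StatSummary(
        names=model.output_names, mu=mu, sigma=sigma, pi95=pi95,
        skewness=skew, kurtosis=kurt, n_samples=n_mc,
    )


@dataclass
class SobolResult:
    """Main and total variance-based sensitivity indices.

    For an orthonormal PCE these are exact: S_i sums squared coefficients
    of multi-indices supported only on input i; S_iT those involving i.
    """

    input_names: tuple[str, ...]
    output_names: tuple[str, ...]
    main: np.ndarray      # (d, n_outputs)
    total: np.ndarray     # (d, n_outputs)
    variance: np.ndarray  # (n_outputs,)


def sobol_indices(
    model: SurrogateModel, input_names: tuple[str, ...] | None = None
) -> SobolResult:
    c2 = model.coefficients[1:] ** 2
    V = c2.sum(axis=0)
    if np.any(V <= 0):
        raise ValueError("zero output variance: Sobol indices undefined")
    idx = model.basis.indices[1:]
    d = model.d
    main = np.empty((d, len(V)))
    total = np.empty_like(main)
    for i in range(d):
        only_i = (idx[:, i] > 0) & (idx.sum(axis=1) == idx[:, i])
        any_i = idx[:, i] > 0
        main[i] = c2[only_i].sum(axis=0) / V
        total[i] = c2[any_i].sum(axis=0) / V
    names = input_names or tuple(f"x{j}" for j in range(d))
    return SobolResult(
        input_names=tuple(names), output_names=model.output_names,
        main=main, total=total, variance=V,
    )


def qmc_estimate(
    forward,
    rv: RandomVector,
    n: int,
    output_names: tuple[str, ...] | None = None,
    skip: int = 0,
) -> StatSummary:
    """Plug-in moment estimates over n Halton points through the forward map.

    ``forward`` maps one physical input vector to an output vector. Failed
    evaluations are logged and skipped; the skip count is reported via the
    ``n_samples`` field (successful evaluations only).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    xi = halton_standard_normal(rv.d, n, skip=skip)
    eta = rv.to_physical(xi)
    ys, n_failed = [], 0
    for k in range(n):
        try:
            ys.append(np.asarray(forward(eta[k]), float))
        except Exception:                                    # noqa: BLE001
            n_failed += 1
            logger.warning("qmc_estimate: forward model failed at point %d", k)
    if n_failed:
        logger.warning("qmc_estimate: skipped %d of %d points", n_failed, n)
    y = np.vstack(ys)
    mu = y.mean(axis=0)
    sigma = y.std(axis=0, ddof=1)
    pi95 = np.percentile(y, [2.5, 97.5], axis=0).T
    skew = stats.skew(y, axis=0)
    kurt = stats.kurtosis(y, axis=0)
    names = output_names or tuple(f"y{k}" for k in range(y.shape[1]))
    return StatSummary(
        names=tuple(names), mu=mu, sigma=sigma, pi95=pi95,
        skewness=skew, kurtosis=kurt, n_samples=len(y),
    )
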