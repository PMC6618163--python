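"""Experiment orchestration: the two uncertainty models, surrogate
calibration, and report generation.

Model A treats nine scalar inputs as random (five Guccione material
parameters and four fiber-angle boundary values); model B fixes those at
their means and perturbs the local fiber orientation with a truncated
Karhunen-Loeve Gaussian field. Both propagate uncertainty through the
same passive-inflation forward model with an order-N Hermite PCE fitted
at N_s = 2M Halton collocation points, validated against held-out solves
and optionally against direct quasi-Monte Carlo estimates.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd

from .fibers import AngleBC, FiberFrameField, assign_fiber_frame, solve_transmural_coordinate
from .geometry import LVGeometryConfig, Mesh, build_idealized_lv
from .mechanics import (
    BoundaryConditionConfig,
    GuccioneParameters,
    NonConvergenceError,
    solve_passive_inflation,
)
from .qoi import QoISet, compute_qois
from .randomfield import (
    CovarianceModel,
    KLEBasis,
    assemble_operators,
    perturb_fiber_frame,
    sample_field,
    solve_kle,
    truncate_by_error_variance,
)
from .uq import (
    InputSpec,
    RandomVector,
    StatSummary,
    SurrogateModel,
    build_pce_basis,
    build_random_vector,
    fit_point_collocation,
    halton_standard_normal,
    qmc_estimate,
    sobol_indices,
    surrogate_statistics,
    validation_rmse,
)

logger = logging.getLogger(__name__)

QOI_NAMES = QoISet.NAMES

#: report units: cavity and wall volume in 10^2 cm^3 / 10 cm^3, thickness
#: in 10^-1 cm, lengthening in cm
QOI_UNIT_SCALE = {"Q_c": 1e-2, "Q_l": 1.0, "Q_t": 10.0, "Q_v": 0.1}
QOI_UNIT_LABEL = {
    "Q_c": "10^2 cm^3", "Q_l": "cm", "Q_t": "10^-1 cm", "Q_v": "10 cm^3",
}


def material_and_angle_inputs() -> list[InputSpec]:
    """The nine scalar random inputs of model A.

    Stiffness exponents are normal; the positive multiplicative and
    incompressibility factors lognormal; fiber angles normal with a 0.15
    coefficient of variation.
    """
    return [
        InputSpec("b_ff", "normal", 6.6, 0.99),
        InputSpec("b_xx", "normal", 4.0, 0.6),
        InputSpec("b_fx", "normal", 2.6, 0.39),
        InputSpec("K", "lognormal", 10.0, 1.5),
        InputSpec("C", "lognormal", 1.1, 0.165),
        InputSpec("alpha_endo", "normal", 50.0, 7.5),
        InputSpec("alpha_epi", "normal", -50.0, 7.5),
        InputSpec("beta_endo", "normal", -65.0, 9.75),
        InputSpec("beta_epi", "normal", 25.0, 3.75),
    ]


@dataclass
class ExperimentConfig:
    """Configuration of one uncertainty-propagation experiment."""

    model: str = "A"                        # "A" | "B"
    geometry: LVGeometryConfig = dfield(default_factory=LVGeometryConfig)
    loading: BoundaryConditionConfig = dfield(default_factory=BoundaryConditionConfig)
    material: GuccioneParameters = dfield(default_factory=GuccioneParameters)
    angles: AngleBC = dfield(default_factory=AngleBC)
    inputs: tuple[InputSpec, ...] | None = None   # defaults to the nine-input table
    pce_order: int = 2
    ns_rule: int = 2                        # N_s = ns_rule * M
    n_validation: int = 16                  # held-out forward solves for RMSE
    qmc_samples: int = 0                    # 0 disables the direct QMC check
    surrogate_mc: int = 100_000
    seed: int = 0
    # model B settings
    sigma_kl: float = 0.1                   # radians
    correlation_lengths: tuple[float, ...] = (10.0, 5.0, 3.0)   # cm
    kle_modes: int = 60
    kle_threshold: float = 0.05
    kle_fraction: float = 0.92

    def __post_init__(self):
        if self.model not in ("A", "B"):
            raise ValueError("model must be 'A' or 'B'")

    def digest(self) -> str:
        blob = json.dumps(
            {k: str(v) for k, v in dataclasses.asdict(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class ForwardSolver:
    """The deterministic forward map eta -> QoIs on a fixed mesh.

    Caches the mesh, transmural coordinate and (for model B) the
    mean-parameter fiber frame; failed solves are retried once with
    doubled load steps before the failure propagates.
    """

    def __init__(self, config: ExperimentConfig, mesh: Mesh | None = None):
        self.config = config
        self.mesh = mesh if mesh is not None else build_idealized_lv(config.geometry)
        self.transmural = solve_transmural_coordinate(self.mesh)
        self.mean_params = config.material
        self.mean_angles = config.angles
        self._mean_frame: FiberFrameField | None = None
        self.n_solves = 0

    @property
    def mean_frame(self) -> FiberFrameField:
        if self._mean_frame is None:
            self._mean_frame = assign_fiber_frame(
                self.mesh, self.transmural, self.mean_angles
            )
        return self._mean_frame

    def _solve(self, frame: FiberFrameField, params: GuccioneParameters) -> QoISet:
        bc = self.config.loading
        try:
            disp = solve_passive_inflation(self.mesh, frame, params, bc)
        except NonConvergenceError:
            logger.warning("retrying a forward solve with doubled load steps")
            bc2 = dataclasses.replace(bc, n_load_steps=2 * bc.n_load_steps)
            disp = solve_passive_inflation(self.mesh, frame, params, bc2)
        self.n_solves += 1
        return compute_qois(self.mesh, disp)

    def solve_material_sample(self, eta: np.ndarray) -> QoISet:
        """Model A: eta = (b_ff, b_xx, b_fx, K, C, a_endo, a_epi, b_endo, b_epi)."""
        eta = np.asarray(eta, float)
        params = GuccioneParameters(
            C=eta[4], b_ff=eta[0], b_xx=eta[1], b_fx=eta[2], K=eta[3]
        )
        angles = AngleBC(
            alpha_endo=eta[5], alpha_epi=eta[6], beta_endo=eta[7], beta_epi=eta[8]
        )
        frame = assign_fiber_frame(self.mesh, self.transmural, angles)
        return self._solve(frame, params)

    def solve_field_sample(self, basis: KLEBasis, eta: np.ndarray) -> QoISet:
        """Model B: eta are the n_KL standard-normal field coordinates."""
        sample = sample_field(basis, eta=np.asarray(eta, float))
        frame = perturb_fiber_frame(self.mean_frame, sample)
        return self._solve(frame, self.mean_params)


@dataclass
class RunReport:
    """Everything one experiment produced, with provenance."""

    model: str
    stats: pd.DataFrame             # per QoI (and per case for model B)
    sobol: pd.DataFrame | None
    validation: pd.DataFrame
    sigma_discrepancy: pd.DataFrame | None
    provenance: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.stats.to_csv(outdir / "stats.csv", index=False)
        if self.sobol is not None:
            self.sobol.to_csv(outdir / "sobol.csv", index=False)
        self.validation.to_csv(outdir / "validation.csv", index=False)
        if self.sigma_discrepancy is not None:
            self.sigma_discrepancy.to_csv(outdir / "qmc_check.csv", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)


def _stats_rows(stats: StatSummary, extra: dict | None = None) -> list[dict]:
    rows = []
    for k, name in enumerate(stats.names):
        sc = QOI_UNIT_SCALE.get(name, 1.0)
        rows.append({
            **(extra or {}),
            "qoi": name,
            "unit": QOI_UNIT_LABEL.get(name, ""),
            "mu": stats.mu[k] * sc,
            "sigma": stats.sigma[k] * sc,
            "cov": stats.sigma[k] / abs(stats.mu[k]),
            "pi95_lo": stats.pi95[k, 0] * sc,
            "pi95_hi": stats.pi95[k, 1] * sc,
            "skewness": stats.skewness[k],
            "kurtosis": stats.kurtosis[k],
            "normal_screen": bool(
                abs(stats.skewness[k]) <= 1.96 and abs(stats.kurtosis[k]) <= 1.96
            ),
        })
    return rows


def _evaluate_forward(solver, xi, rv, which="A", basis=None):
    out = np.empty((len(xi), len(QOI_NAMES)))
    for k in range(len(xi)):
        if which == "A":
            out[k] = solver.solve_material_sample(rv.to_physical(xi[k])[0]).as_array()
        else:
            out[k] = solver.solve_field_sample(basis, xi[k]).as_array()
    return out


def fit_model_a_surrogate(
    config: ExperimentConfig, solver: ForwardSolver | None = None
) -> tuple[SurrogateModel, RandomVector, ForwardSolver]:
    """Collocation solves and PCE fit for model A (no statistics yet)."""
    solver = solver or ForwardSolver(config)
    rv = build_random_vector(list(config.inputs or material_and_angle_inputs()))
    basis = build_pce_basis(rv, config.pce_order)
    n_s = config.ns_rule * basis.M
    xi = halton_standard_normal(rv.d, n_s)
    logger.info("model A: %d collocation solves (M=%d)", n_s, basis.M)
    evals = _evaluate_forward(solver, xi, rv, "A")
    model = fit_point_collocation(basis, xi, evals, output_names=QOI_NAMES)
    return model, rv, solver


def run_model_a(config: ExperimentConfig, solver: ForwardSolver | None = None) -> RunReport:
    """Full model-A experiment: PCE, statistics, Sobol indices, validation."""
    model, rv, solver = fit_model_a_surrogate(config, solver)
    stats = surrogate_statistics(model, config.surrogate_mc, config.seed)
    sob = sobol_indices(model, tuple(s.name for s in rv.specs))

    # held-out RMSE on fresh points further down the same Halton sequence
    val_rows = []
    if config.n_validation > 0:
        xi_val = halton_standard_normal(rv.d, config.n_validation, skip=model.n_samples)
        evals_val = _evaluate_forward(solver, xi_val, rv, "A")
        rmse = validation_rmse(model, xi_val, evals_val)
        for k, name in enumerate(QOI_NAMES):
            val_rows.append({
                "qoi": name, "rmse": rmse[k] * QOI_UNIT_SCALE[name],
                "unit": QOI_UNIT_LABEL[name], "n_heldout": config.n_validation,
                "condition_number": model.condition_number,
            })

    disc = None
    if config.qmc_samples > 0:
        qstats = qmc_estimate(
            lambda eta: solver.solve_material_sample(eta).as_array(),
            rv, config.qmc_samples, output_names=QOI_NAMES,
        )
        disc = pd.DataFrame({
            "qoi": QOI_NAMES,
            "sigma_pce": model.std() * [QOI_UNIT_SCALE[n] for n in QOI_NAMES],
            "sigma_qmc": qstats.sigma * [QOI_UNIT_SCALE[n] for n in QOI_NAMES],
            "rel_discrepancy_pct":
                100.0 * np.abs(model.std() - qstats.sigma) / qstats.sigma,
            "n_qmc": config.qmc_samples,
        })

    sob_df = pd.DataFrame([
        {"input": sob.input_names[i], "qoi": sob.output_names[k],
         "S_main": sob.main[i, k], "S_total": sob.total[i, k]}
        for i in range(len(sob.input_names))
        for k in range(len(sob.output_names))
    ])
    prov = {
        "model": "A", "seed": config.seed, "config_digest": config.digest(),
        "n_collocation": model.n_samples, "condition_number": model.condition_number,
        "n_forward_solves": solver.n_solves,
        "mesh": {"n_vertices": solver.mesh.n_vertices, "n_cells": len(solver.mesh.cells)},
    }
    return RunReport(
        model="A",
        stats=pd.DataFrame(_stats_rows(stats)),
        sobol=sob_df,
        validation=pd.DataFrame(val_rows),
        sigma_discrepancy=disc,
        provenance=prov,
    )


def build_kle_for_length(
    config: ExperimentConfig, mesh: Mesh, l: float, sigma_kl: float | None = None
) -> KLEBasis:
    """Assemble, solve and truncate the KLE for one correlation length."""
    cov = CovarianceModel(sigma_kl=sigma_kl or config.sigma_kl, l=l)
    ops = assemble_operators(mesh, cov)
    basis = solve_kle(ops, min(config.kle_modes, mesh.n_vertices - 1))
    n_kl = truncate_by_error_variance(
        basis, cov, threshold=config.kle_threshold, fraction=config.kle_fraction
    )
    return basis.truncated(n_kl)


def run_model_b(config: ExperimentConfig, solver: ForwardSolver | None = None) -> RunReport:
    """Model-B experiment over the configured correlation lengths."""
    solver = solver or ForwardSolver(config)
    stats_rows, val_rows, disc_rows = [], [], []
    for l in config.correlation_lengths:
        basis = build_kle_for_length(config, solver.mesh, l)
        d = basis.n_kl
        pce = build_pce_basis(d, config.pce_order)
        n_s = config.ns_rule * pce.M
        logger.info("model B l=%g: n_KL=%d, %d collocation solves", l, d, n_s)
        xi = halton_standard_normal(d, n_s)
        evals = _evaluate_forward(solver, xi, None, "B", basis)
        model = fit_point_collocation(pce, xi, evals, output_names=QOI_NAMES)
        stats = surrogate_statistics(model, config.surrogate_mc, config.seed)
        stats_rows += _stats_rows(
            stats, {"l": l, "sigma_kl": config.sigma_kl, "n_kl": d}
        )
        if config.n_validation > 0:
            xi_val = halton_standard_normal(d, config.n_validation, skip=n_s)
            evals_val = _evaluate_forward(solver, xi_val, None, "B", basis)
            rmse = validation_rmse(model, xi_val, evals_val)
            for k, name in enumerate(QOI_NAMES):
                val_rows.append({
                    "l": l, "sigma_kl": config.sigma_kl, "qoi": name,
                    "rmse": rmse[k] * QOI_UNIT_SCALE[name],
                    "unit": QOI_UNIT_LABEL[name],
                    "condition_number": model.condition_number,
                })
        if config.qmc_samples > 0:
            std_rv = build_random_vector(
                [InputSpec(f"eta_{k}", "normal", 0.0, 1.0) for k in range(d)]
            )
            qstats = qmc_estimate(
                lambda eta: solver.solve_field_sample(basis, eta).as_array(),
                std_rv, config.qmc_samples, output_names=QOI_NAMES,
            )
            for k, name in enumerate(QOI_NAMES):
                disc_rows.append({
                    "l": l, "sigma_kl": config.sigma_kl, "qoi": name,
                    "sigma_pce": model.std()[k] * QOI_UNIT_SCALE[name],
                    "sigma_qmc": qstats.sigma[k] * QOI_UNIT_SCALE[name],
                    "rel_discrepancy_pct":
                        100.0 * abs(model.std()[k] - qstats.sigma[k]) / qstats.sigma[k],
                })
    prov = {
        "model": "B", "seed": config.seed, "config_digest": config.digest(),
        "sigma_kl": config.sigma_kl,
        "correlation_lengths": list(config.correlation_lengths),
        "n_forward_solves": solver.n_solves,
        "mesh": {"n_vertices": solver.mesh.n_vertices, "n_cells": len(solver.mesh.cells)},
    }
    return RunReport(
        model="B",
        stats=pd.DataFrame(stats_rows),
        sobol=None,
        validation=pd.DataFrame(val_rows),
        sigma_discrepancy=pd.DataFrame(disc_rows) if disc_rows else None,
        provenance=prov,
    )


def calibration_sweep(
    forward,
    d: int,
    orders: tuple[int, ...] = (1, 2),
    rules: tuple[int, ...] = (2, 3, 4),
    n_heldout: int = 20,
    output_names: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Held-out RMSE over a grid of PCE order and sampling rule.

    ``forward`` maps a standardized point (d,) to an output vector; the
    forward evaluations at the union of all needed Halton points are
    computed once and shared across the grid.
    """
    n_pool = max(r * build_pce_basis(d, N).M for N in orders for r in rules)
    xi_pool = halton_standard_normal(d, n_pool)
    xi_val = halton_standard_normal(d, n_heldout, skip=n_pool)
    y_pool = np.vstack([np.atleast_1d(forward(x)) for x in xi_pool])
    y_val = np.vstack([np.atleast_1d(forward(x)) for x in xi_val])
    names = output_names or tuple(f"y{k}" for k in range(y_pool.shape[1]))
    rows = []
    for N in orders:
        basis = build_pce_basis(d, N)
        for r in rules:
            n_s = r * basis.M
            model = fit_point_collocation(
                basis, xi_pool[:n_s], y_pool[:n_s], output_names=names
            )
            rmse = validation_rmse(model, xi_val, y_val)
            for k, name in enumerate(names):
                rows.append({
                    "N": N, "ns_rule": f"{r}M", "N_s": n_s, "qoi": name,
                    "rmse": rmse[k], "condition_number": model.condition_number,
                })
    return pd.DataFrame(rows)
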