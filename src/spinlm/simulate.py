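"""Synthetic spatial surfaces, covariates/response generation and the
simulation harness.

Two error-surface generators on the unit square:

GEOSTAT
    Exact Gaussian-process simulation: the error vector at all observed and
    grid sites jointly is ``eps = L z`` with ``V = L L'`` the Cholesky factor
    of a spherical-covariance matrix (defaults: partial sill 10, nugget 0.1).
    Simulating observed and grid sites from one factorization gives the
    predictions a correlated truth, which honest prediction-error and
    interval-coverage summaries require.  Cubic cost limits the total number
    of sites (guard at 6000).

SUMSINE
    A sum of 100 randomly rotated two-dimensional sine components with
    linearly decreasing expected amplitude and increasing frequency, linear
    in the number of sites (no matrix is ever formed).  Each realization is
    standardized to mean 0 and variance 10, then independent noise of
    variance 0.1 is added per site, playing the role of a nugget.  All
    underlying uniforms are U(0, 1).

Responses follow ``y = b0 + b1*x1 + b2*x2 + eps`` with b = (1, 1, 1), where
x1 is i.i.d. standard normal and x2 is an independent realization of the
same surface generator (a spatially patterned covariate).

``run_experiment`` draws replicate datasets, fits the blocked model under a
(deliberately misspecified) exponential covariance, and records fixed-effect
estimates, point predictions and block predictions for one or more designs,
sharing the simulated data across designs within a replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .blockpredict import block_predict, block_variance, make_grid
from .covariance import CovarianceSpec, build_cov_matrix
from .estimate import (
    SpatialDataset,
    estimate_var_beta,
    fit_fixed_effects,
    fit_reml,
)
from .partition import partition_compact, partition_mixed, partition_random
from .predict import point_predict_global, point_predict_local

__all__ = [
    "SimulationConfig",
    "SimulatedSurface",
    "ExperimentDesign",
    "simulate_surface",
    "simulate_geostat",
    "simulate_sumsine",
    "make_covariates_and_response",
    "metrics",
    "run_experiment",
    "summarize_experiment",
    "mixed_sim",
    "benchmark_sim",
    "sumsine_sim",
]

logger = logging.getLogger(__name__)

_GEOSTAT_GUARD = 6000
_N_SINE_COMPONENTS = 100
_SUMSINE_VARIANCE = 10.0
_SUMSINE_NUGGET = 0.1


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one simulated dataset.

    ``n`` observed locations are drawn uniformly on the unit square and a
    ``grid_resolution`` x ``grid_resolution`` prediction grid is appended.
    ``theta`` parameterises the GEOSTAT spherical model (partial sill,
    nugget, range).  ``standardize`` rescales the error surface (and the
    spatially patterned covariate) to unit variance before the fixed effects
    are added.
    """

    method: str
    n: int
    seed: int
    grid_resolution: int = 40
    theta: tuple[float, float, float] = (10.0, 0.1, 0.5)
    beta: tuple[float, float, float] = (1.0, 1.0, 1.0)
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("geostat", "sumsine"):
            raise ValueError(f"unknown simulation method {self.method!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class SimulatedSurface:
    """One realization: coordinates (observed first, then grid), error
    surface, covariates and response at every site."""

    config: SimulationConfig
    coords: np.ndarray
    epsilon: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    y: np.ndarray

    @property
    def n_obs(self) -> int:
        return self.config.n

    def observed(self) -> SpatialDataset:
        n = self.n_obs
        x = np.column_stack([np.ones(n), self.x1[:n], self.x2[:n]])
        return SpatialDataset(self.coords[:n], x, self.y[:n])

    def grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Grid coordinates, grid design matrix and realized grid values."""
        n = self.n_obs
        x = np.column_stack(
            [np.ones(len(self.y) - n), self.x1[n:], self.x2[n:]]
        )
        return self.coords[n:], x, self.y[n:]


def _site_coords(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    obs = rng.uniform(0.0, 1.0, size=(config.n, 2))
    if config.grid_resolution >= 1:
        grid = make_grid((0.0, 1.0, 0.0, 1.0), config.grid_resolution).grid_points
        return np.vstack([obs, grid])
    return obs


def _standardize(v: np.ndarray, target_var: float = 1.0) -> np.ndarray:
    return (v - v.mean()) / v.std() * np.sqrt(target_var)


def _geostat_fields(coords, theta, rng, n_fields=2):
    spec = CovarianceSpec("spherical", *theta)
    v = build_cov_matrix(coords, spec, check=False)
    chol = np.linalg.cholesky(v)
    return [chol @ rng.standard_normal(coords.shape[0]) for _ in range(n_fields)]


def _sumsine_smooth(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Standardized sum-of-random-sines surface (mean 0, variance 10)."""
    total = np.zeros(coords.shape[0])
    for i in range(1, _N_SINE_COMPONENTS + 1):
        u1, u2, u3, u4, u5, u6 = rng.uniform(size=6)
        angle = u1 * np.pi
        ca, sa = np.cos(angle), np.sin(angle)
        s1 = coords[:, 0] * ca + coords[:, 1] * sa
        s2 = -coords[:, 0] * sa + coords[:, 1] * ca
        amp = u2 * (1.0 - (i - 1) / _N_SINE_COMPONENTS)
        total += amp * (
            np.sin(i * u3 * 2.0 * np.pi * (s1 + u4 * np.pi))
            + np.sin(i * u5 * 2.0 * np.pi * (s2 + u6 * np.pi))
        )
    return _standardize(total, _SUMSINE_VARIANCE)


def _sumsine_field(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    smooth = _sumsine_smooth(coords, rng)
    return smooth + rng.normal(0.0, np.sqrt(_SUMSINE_NUGGET), size=coords.shape[0])


def simulate_geostat(config: SimulationConfig, rng=None) -> SimulatedSurface:
    """Exact Cholesky-based simulation from the spherical model at all
    observed + grid sites jointly."""
    if config.method != "geostat":
        raise ValueError("config.method must be 'geostat'")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    coords = _site_coords(config, rng)
    if coords.shape[0] > _GEOSTAT_GUARD:
        raise ValueError(
            f"{coords.shape[0]} sites exceed the dense-Cholesky guard "
            f"({_GEOSTAT_GUARD}); use the sumsine method for larger surfaces"
        )
    eps, x2 = _geostat_fields(coords, config.theta, rng)
    if config.standardize:
        eps, x2 = _standardize(eps), _standardize(x2)
    return make_covariates_and_response(coords, eps, x2, config, rng)


def simulate_sumsine(config: SimulationConfig, rng=None) -> SimulatedSurface:
    """Random sine-wave surface; linear cost, suitable for very large n."""
    if config.method != "sumsine":
        raise ValueError("config.method must be 'sumsine'")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    coords = _site_coords(config, rng)
    eps = _sumsine_field(coords, rng)
    x2 = _sumsine_field(coords, rng)
    if config.standardize:
        eps, x2 = _standardize(eps), _standardize(x2)
    return make_covariates_and_response(coords, eps, x2, config, rng)


def make_covariates_and_response(
    coords: np.ndarray,
    epsilon: np.ndarray,
    x2: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SimulatedSurface:
    """Attach the i.i.d.-normal covariate and build the response
    ``y = b0 + b1 x1 + b2 x2 + eps`` at every site."""
    x1 = rng.standard_normal(coords.shape[0])
    b0, b1, b2 = config.beta
    y = b0 + b1 * x1 + b2 * x2 + epsilon
    return SimulatedSurface(config, coords, epsilon, x1, x2, y)


def simulate_surface(config: SimulationConfig) -> SimulatedSurface:
    """Dispatch on ``config.method``."""
    if config.method == "geostat":
        return simulate_geostat(config)
    return simulate_sumsine(config)


def metrics(true_values, estimates, ses=None) -> dict:
    """Simulation summaries: root-mean-squared error and, when standard
    errors are supplied, empirical coverage of nominal 90% intervals formed
    with the 1.645 normal quantile.

    For fixed effects these are the RMSE/CI90 summaries; applied to
    predictions they are RMSPE/PI90 (identical formulas).
    """
    true_values = np.asarray(true_values, dtype=float).ravel()
    estimates = np.asarray(estimates, dtype=float).ravel()
    if true_values.shape != estimates.shape:
        raise ValueError("true values and estimates must have the same length")
    err = estimates - true_values
    out = {"rmse": float(np.sqrt(np.mean(err**2)))}
    if ses is not None:
        ses = np.asarray(ses, dtype=float).ravel()
        if ses.shape != estimates.shape:
            raise ValueError("ses must match the estimates in length")
        out["coverage90"] = float(np.mean(np.abs(err) <= 1.645 * ses))
    return out


# ---------------------------------------------------------------------------
# experiment harness


@dataclass(frozen=True)
class ExperimentDesign:
    """One analysis recipe applied to every simulated replicate.

    Partition sizes may be an int or an inclusive (low, high) range drawn
    per replicate.  ``var_estimators`` selects which covariance estimators
    of beta_bd to evaluate; point prediction uses the first one listed.
    """

    name: str = "design"
    cope_method: str = "comp"
    fefe_method: str = "comp"
    cope_size: int | tuple[int, int] = 50
    fefe_size: int | tuple[int, int] = 50
    n_neighbors: tuple[int, ...] = (50,)
    modes: tuple[str, ...] = ("global",)
    var_estimators: tuple[str, ...] = ("exact",)
    block: bool = False
    family: str = "exponential"
    block_subsample_cap: int | None = None


def mixed_sim(rng: np.random.Generator, grid_resolution: int = 40) -> SimulationConfig:
    """The wide-ranging replicate draw: a fair coin between GEOSTAT with
    n ~ U{1000..2000}, range ~ U(0, 2), and SUMSINE with n ~ U{2000..10000}."""
    seed = int(rng.integers(2**31))
    if rng.random() < 0.5:
        n = int(rng.integers(1000, 2001))
        rho = float(rng.uniform(0.0, 2.0))
        return SimulationConfig(
            "geostat", n, seed, grid_resolution, theta=(10.0, 0.1, rho)
        )
    n = int(rng.integers(2000, 10001))
    return SimulationConfig("sumsine", n, seed, grid_resolution)


def benchmark_sim(rng: np.random.Generator, grid_resolution: int = 40) -> SimulationConfig:
    """Fixed-size GEOSTAT benchmark: n = 1000, spherical partial sill 10,
    range 0.5, nugget 0.1, errors standardized before adding fixed effects."""
    seed = int(rng.integers(2**31))
    return SimulationConfig(
        "geostat", 1000, seed, grid_resolution, theta=(10.0, 0.1, 0.5), standardize=True
    )


def sumsine_sim(n_range: tuple[int, int], grid_resolution: int = 40):
    """SUMSINE replicates with n drawn uniformly from an inclusive range."""

    def draw(rng: np.random.Generator) -> SimulationConfig:
        seed = int(rng.integers(2**31))
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        return SimulationConfig("sumsine", n, seed, grid_resolution)

    return draw


_PARTITIONERS = {
    "rand": partition_random,
    "comp": partition_compact,
    "mixd": partition_mixed,
}


def _draw_size(size, rng) -> int:
    if isinstance(size, tuple):
        return int(rng.integers(size[0], size[1] + 1))
    return int(size)


def run_experiment(
    sim,
    designs,
    reps: int,
    seed: int,
    predict_grid: bool = True,
    progress: bool = False,
) -> pd.DataFrame:
    """Run ``reps`` replicates of ``sim`` (a callable rng -> SimulationConfig
    or a fixed SimulationConfig) under one or more designs.

    Every design sees the same simulated data within a replicate (common
    random numbers), and REML fits are shared between designs that request
    the same covariance partition.  Returns a tidy per-replicate frame with
    one row per recorded quantity:

    - kind="beta": coefficient estimate, se and truth per covariate and
      variance estimator;
    - kind="point": per-replicate mean squared prediction error and interval
      coverage over the grid, per neighbor count and predictor mode;
    - kind="block": block prediction, realized block mean and block se.
    """
    if isinstance(designs, ExperimentDesign):
        designs = [designs]
    rows: list[dict] = []
    streams = np.random.SeedSequence(seed).spawn(reps)
    for rep, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        cfg = sim(rng) if callable(sim) else replace(sim, seed=int(rng.integers(2**31)))
        surface = simulate_surface(cfg)
        dataset = surface.observed()
        grid_coords, grid_x, grid_y = surface.grid()
        region = make_grid((0.0, 1.0, 0.0, 1.0), cfg.grid_resolution)
        fit_cache: dict = {}
        for design in designs:
            cope_size = _draw_size(design.cope_size, rng)
            if design.fefe_size == design.cope_size:
                fefe_size = cope_size
            else:
                fefe_size = _draw_size(design.fefe_size, rng)
            key = (design.cope_method, cope_size, design.family)
            if key not in fit_cache:
                part = _PARTITIONERS[design.cope_method](
                    dataset.coords, cope_size, seed=int(rng.integers(2**31))
                )
                fit_cache[key] = fit_reml(dataset, part, family=design.family)
            cope_fit = fit_cache[key]
            if (design.fefe_method, fefe_size) == (design.cope_method, cope_size):
                fefe_fit = cope_fit
            else:
                part_f = _PARTITIONERS[design.fefe_method](
                    dataset.coords, fefe_size, seed=int(rng.integers(2**31))
                )
                fefe_fit = fit_fixed_effects(dataset, part_f, cope_fit.spec)
            base = {
                "rep": rep,
                "design": design.name,
                "sim": cfg.method,
                "n": cfg.n,
                "cope_size": cope_size,
                "fefe_size": fefe_size,
            }
            var_results = {
                est: estimate_var_beta(fefe_fit, est) for est in design.var_estimators
            }
            for est, res in var_results.items():
                for coef in range(1, dataset.n_covariates):
                    rows.append(
                        base
                        | {
                            "kind": "beta",
                            "estimator": est,
                            "coef": coef,
                            "estimate": float(res.beta[coef]),
                            "se": float(res.se[coef]),
                            "true": float(cfg.beta[coef]),
                        }
                    )
            if not predict_grid:
                continue
            c_hat = var_results[design.var_estimators[0]]
            for m in design.n_neighbors:
                for mode in design.modes:
                    if mode == "global":
                        pr = point_predict_global(
                            dataset, fefe_fit, grid_coords, grid_x, m, c_hat
                        )
                    else:
                        pr = point_predict_local(
                            dataset, cope_fit.spec, grid_coords, grid_x, m
                        )
                    err = pr.predictions - grid_y
                    rows.append(
                        base
                        | {
                            "kind": "point",
                            "mode": mode,
                            "m": m,
                            "mspe": float(np.mean(err**2)),
                            "cover": float(np.mean(np.abs(err) <= 1.645 * pr.pred_se)),
                        }
                    )
                if design.block and "global" in design.modes:
                    bp = block_predict(dataset, fefe_fit, region, grid_x, m, c_hat)
                    bv = block_variance(
                        dataset,
                        fefe_fit,
                        region,
                        bp.a_star,
                        subsample_cap=design.block_subsample_cap,
                        seed=int(rng.integers(2**31)),
                    )
                    rows.append(
                        base
                        | {
                            "kind": "block",
                            "m": m,
                            "estimate": bp.prediction,
                            "true": float(np.mean(grid_y)),
                            "se": float(np.sqrt(bv)),
                        }
                    )
        if progress:
            logger.info("replicate %d/%d done", rep + 1, reps)
    return pd.DataFrame(rows)


def summarize_experiment(results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Collapse a per-replicate results frame into the usual simulation
    summaries (RMSE/CI90 for coefficients, RMSPE/PI90 for predictions)."""
    out: dict[str, pd.DataFrame] = {}
    beta = results[results["kind"] == "beta"]
    if len(beta):
        err2 = (beta["estimate"] - beta["true"]) ** 2
        cover = (np.abs(beta["estimate"] - beta["true"]) <= 1.645 * beta["se"]).astype(float)
        grp = beta.assign(err2=err2, cover=cover).groupby(
            ["design", "estimator", "coef"], sort=True
        )
        out["beta"] = grp.agg(
            rmse=("err2", lambda v: float(np.sqrt(np.mean(v)))),
            ci90=("cover", "mean"),
            reps=("err2", "size"),
        ).reset_index()
    point = results[results["kind"] == "point"]
    if len(point):
        grp = point.groupby(["design", "mode", "m"], sort=True)
        out["point"] = grp.agg(
            rmspe=("mspe", lambda v: float(np.sqrt(np.mean(v)))),
            pi90=("cover", "mean"),
            reps=("mspe", "size"),
        ).reset_index()
    block = results[results["kind"] == "block"]
    if len(block):
        err2 = (block["estimate"] - block["true"]) ** 2
        cover = (np.abs(block["estimate"] - block["true"]) <= 1.645 * block["se"]).astype(float)
        grp = block.assign(err2=err2, cover=cover).groupby(["design", "m"], sort=True)
        out["block"] = grp.agg(
            rmspe=("err2", lambda v: float(np.sqrt(np.mean(v)))),
            pi90=("cover", "mean"),
            reps=("err2", "size"),
        ).reset_index()
    return out
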