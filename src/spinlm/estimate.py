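"""Blocked REML estimation of covariance parameters and pooled fixed effects.

The spatial linear model is ``y = X beta + eps`` with ``var(eps) = V`` built
from a stationary covariance function.  For large n, V is indexed into P
blocks and replaced by its block-diagonal part ``V_part = diag(V_11 .. V_PP)``
during estimation, so only block-sized matrices are ever factorised.

* Covariance parameters theta minimise the REML criterion evaluated under
  ``V_part`` (additive constant dropped)::

      sum_i log|V_ii| + r' V_part^{-1} r + log| sum_i X_i' V_ii^{-1} X_i |

  with ``r = y - X beta_theta`` and ``beta_theta`` the blocked GLS estimate
  at theta.  Note the pooled log-determinant of the information matrix: this
  differs from composite likelihood, which sums per-block log-determinants
  and therefore breaks when a block's design matrix has all-zero columns.

* Fixed effects use the pooled estimator ``beta_bd = T_xx^{-1} t_xy`` with
  ``T_xx = sum_i X_i' V_ii^{-1} X_i`` and ``t_xy = sum_i X_i' V_ii^{-1} y_i``.
  Because beta_bd is linear in y (``beta_bd = Q y``), its variance can be
  evaluated *exactly* under the full (unpartitioned) covariance matrix:

      var(beta_bd) = T_xx^{-1} + T_xx^{-1} W_xx T_xx^{-1}

  where W_xx accumulates the cross-block terms
  ``X_i' V_ii^{-1} V_ij V_jj^{-1} X_j`` over all pairs i < j.  Two cheaper
  estimators are available: the empirical spread of per-block GLS estimates,
  and the average of per-block information-matrix inverses.

All heavy work is done on padded (P, s, s) arrays so that Cholesky
factorizations, solves and inner products run batched over blocks.  Padded
rows carry a unit diagonal, zero covariates and zero responses, which leaves
every REML term exactly unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from scipy.special import ndtr

from .covariance import CovarianceSpec, NumericalDegeneracyError, diag_value, family_values
from .partition import PartitionIndex

__all__ = [
    "SpatialDataset",
    "BlockedFit",
    "FixedEffectsResult",
    "reml_objective_blocked",
    "fit_reml",
    "fit_fixed_effects",
    "var_beta_exact",
    "var_beta_empirical",
    "var_beta_pooled",
    "wald_table",
]

logger = logging.getLogger(__name__)

_PENALTY = 1e10
_LOG_CLIP = 40.0


@dataclass
class SpatialDataset:
    """Point-referenced data: coordinates, design matrix and response."""

    coords: np.ndarray
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        n = self.coords.shape[0]
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        if self.X.ndim != 2 or self.X.shape[0] != n or self.y.shape[0] != n:
            raise ValueError("coords, X and y must have matching first dimension")
        if not (np.isfinite(self.coords).all() and np.isfinite(self.X).all() and np.isfinite(self.y).all()):
            raise ValueError("dataset contains non-finite values")
        r = self.X.shape[1]
        if n < r:
            raise ValueError(f"need at least as many observations ({n}) as covariates ({r})")
        if np.linalg.matrix_rank(self.X) < r:
            raise ValueError("design matrix X is rank deficient")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]


class _BlockWorkspace:
    """Padded per-block views of a dataset for batched linear algebra.

    Blocks are padded to the largest block size; pad positions get zero
    covariates/response, zero cross-covariance and a unit diagonal, which is
    equivalent to appending independent unit-variance phantom observations
    with no effect on any blocked quantity.
    """

    def __init__(self, dataset: SpatialDataset, partition: PartitionIndex):
        if partition.n != dataset.n:
            raise ValueError("partition does not cover the dataset")
        self.dataset = dataset
        self.partition = partition
        p = partition.n_blocks
        sizes = partition.sizes
        smax = int(sizes.max())
        idx = np.full((p, smax), -1, dtype=np.intp)
        order = np.argsort(partition.labels, kind="stable")
        starts = np.concatenate(([0], np.cumsum(sizes)))
        for b in range(p):
            idx[b, : sizes[b]] = order[starts[b] : starts[b + 1]]
        mask = idx >= 0
        safe = np.where(mask, idx, 0)
        self.idx, self.mask = idx, mask
        self.sizes = sizes
        self.P, self.smax = p, smax
        self.n, self.R = dataset.n, dataset.n_covariates
        self.coords = dataset.coords[safe]
        self.X = dataset.X[safe] * mask[..., None]
        self.y = dataset.y[safe] * mask
        diff = self.coords[:, :, None, :] - self.coords[:, None, :, :]
        self.D = np.sqrt(np.einsum("pijk,pijk->pij", diff, diff))
        self.pair_mask = mask[:, :, None] & mask[:, None, :]

    def padded_cov(self, spec: CovarianceSpec) -> np.ndarray:
        v = np.asarray(family_values(self.D, spec), dtype=float)
        v *= self.pair_mask
        di = np.arange(self.smax)
        v[:, di, di] = np.where(self.mask, diag_value(spec), 1.0)
        return v

    def scatter_rows(self, values: np.ndarray) -> np.ndarray:
        """Map a padded (P, s, ...) per-observation array back to original
        observation order (n, ...)."""
        out = np.zeros((self.n,) + values.shape[2:], dtype=float)
        out[self.idx[self.mask]] = values[self.mask]
        return out


def _penalty(log_theta: np.ndarray) -> float:
    return _PENALTY + float(np.sum(np.abs(log_theta)))


def _objective_ws(ws: _BlockWorkspace, spec: CovarianceSpec) -> float | None:
    """Blocked REML criterion; None signals a non-PD covariance."""
    v = ws.padded_cov(spec)
    try:
        chol = np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        return None
    logdet_v = 2.0 * float(np.log(np.diagonal(chol, axis1=1, axis2=2)).sum())
    rhs = np.concatenate([ws.X, ws.y[..., None]], axis=2)
    sol = np.linalg.solve(v, rhs)
    sol_x, sol_y = sol[:, :, :-1], sol[:, :, -1]
    t_xx = np.einsum("psi,psj->ij", ws.X, sol_x)
    t_xy = np.einsum("psi,ps->i", ws.X, sol_y)
    y_vy = float(np.einsum("ps,ps->", ws.y, sol_y))
    sign, logdet_t = np.linalg.slogdet(t_xx)
    if sign <= 0 or not np.isfinite(logdet_t):
        return None
    try:
        beta = np.linalg.solve(t_xx, t_xy)
    except np.linalg.LinAlgError:
        return None
    r_vr = y_vy - 2.0 * float(beta @ t_xy) + float(beta @ t_xx @ beta)
    return logdet_v + r_vr + logdet_t


def reml_objective_blocked(
    theta: Sequence[float],
    dataset: SpatialDataset,
    partition: PartitionIndex,
    family="exponential",
) -> float:
    """Blocked REML objective at theta = (tau2, eta2, rho), constant dropped.

    A non-positive-definite block yields a large penalty value rather than an
    exception so derivative-free optimizers can recover.
    """
    spec = CovarianceSpec(family, *theta)
    ws = _BlockWorkspace(dataset, partition)
    value = _objective_ws(ws, spec)
    if value is None:
        return _penalty(np.log(np.asarray(theta, dtype=float)))
    return value


@dataclass
class BlockedFit:
    """Fitted blocked model: theta-hat plus cached per-block pieces.

    ``block_inverses`` holds the padded (P, s, s) inverses of the diagonal
    blocks at theta-hat; ``_G`` holds ``V_ii^{-1} X_i`` which is all that the
    downstream variance estimators and predictors need.
    """

    spec: CovarianceSpec
    partition: PartitionIndex
    T_xx: np.ndarray
    t_xy: np.ndarray
    beta_bd: np.ndarray
    block_inverses: np.ndarray
    objective: float | None
    converged: bool
    n_eval: int = 0
    _ws: _BlockWorkspace = field(repr=False, default=None)
    _G: np.ndarray = field(repr=False, default=None)

    @property
    def dataset(self) -> SpatialDataset:
        return self._ws.dataset

    @property
    def Txx_inv(self) -> np.ndarray:
        inv = np.linalg.inv(self.T_xx)
        return (inv + inv.T) / 2.0

    def q_transpose(self) -> np.ndarray:
        """Transpose of the pooled-estimator matrix Q as an (n, R) array, in
        original observation order: row i is ``V_bb^{-1} X_b T_xx^{-1}`` for
        observation i in block b.  Satisfies ``Q X = I``."""
        g_full = self._ws.scatter_rows(self._G)
        return g_full @ self.Txx_inv

    def block_information(self) -> np.ndarray:
        """Per-block information matrices ``X_i' V_ii^{-1} X_i`` (P, R, R)."""
        return np.einsum("psi,psj->pij", self._ws.X, self._G)

    def per_block_betas(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-block GLS estimates and a validity mask.

        Blocks whose information matrix is (numerically) singular -- e.g. a
        categorical level absent from the block -- are flagged invalid.
        """
        info = self.block_information()
        bxy = np.einsum("psr,ps->pr", self._G, self._ws.y)
        p, r = info.shape[0], info.shape[1]
        betas = np.zeros((p, r))
        valid = np.ones(p, dtype=bool)
        for b in range(p):
            try:
                np.linalg.cholesky(info[b] + 0.0)
                betas[b] = np.linalg.solve(info[b], bxy[b])
            except np.linalg.LinAlgError:
                valid[b] = False
        return betas, valid


def _max_pairwise_distance(coords: np.ndarray) -> float:
    if coords.shape[0] <= 2000:
        return float(pdist(coords).max())
    try:
        hull = coords[ConvexHull(coords).vertices]
        return float(pdist(hull).max())
    except QhullError:  # degenerate (collinear) configurations
        lo, hi = coords.min(axis=0), coords.max(axis=0)
        return float(np.linalg.norm(hi - lo))


def _default_init(dataset: SpatialDataset) -> tuple[float, float, float]:
    beta, *_ = np.linalg.lstsq(dataset.X, dataset.y, rcond=None)
    resid = dataset.y - dataset.X @ beta
    dof = max(dataset.n - dataset.n_covariates, 1)
    s2 = float(resid @ resid) / dof
    s2 = max(s2, 1e-8)
    rho0 = max(0.1 * _max_pairwise_distance(dataset.coords), 1e-8)
    return (s2 / 2.0, s2 / 2.0, rho0)


def _finalize_fit(
    ws: _BlockWorkspace,
    spec: CovarianceSpec,
    objective: float | None,
    converged: bool,
    n_eval: int = 0,
) -> BlockedFit:
    v = ws.padded_cov(spec)
    try:
        np.linalg.cholesky(v)
    except np.linalg.LinAlgError as exc:
        raise NumericalDegeneracyError(
            f"block covariance not positive definite at tau2={spec.tau2:g}, "
            f"eta2={spec.eta2:g}, rho={spec.rho:g}"
        ) from exc
    vinv = np.linalg.inv(v)
    vinv = (vinv + np.swapaxes(vinv, 1, 2)) / 2.0
    g = vinv @ ws.X
    t_xx = np.einsum("psi,psr->ir", ws.X, g)
    t_xx = (t_xx + t_xx.T) / 2.0
    t_xy = np.einsum("psr,ps->r", g, ws.y)
    sign, _ = np.linalg.slogdet(t_xx)
    if sign <= 0:
        diag = np.sqrt(np.clip(np.diag(t_xx), 1e-300, None))
        corr = t_xx / np.outer(diag, diag)
        bad = [j for j in range(t_xx.shape[0]) if np.abs(np.delete(corr[j], j)).max() > 1 - 1e-10]
        raise np.linalg.LinAlgError(
            f"pooled information matrix T_xx is singular; suspect columns {bad}"
        )
    beta = np.linalg.solve(t_xx, t_xy)
    return BlockedFit(
        spec=spec,
        partition=ws.partition,
        T_xx=t_xx,
        t_xy=t_xy,
        beta_bd=beta,
        block_inverses=vinv,
        objective=objective,
        converged=converged,
        n_eval=n_eval,
        _ws=ws,
        _G=g,
    )


def fit_reml(
    dataset: SpatialDataset,
    partition: PartitionIndex,
    family="exponential",
    init: Sequence[float] | None = None,
    optimizer_settings: dict | None = None,
    seed: int | None = None,
) -> BlockedFit:
    """Minimise the blocked REML criterion over log (tau2, eta2, rho).

    Derivative-free Nelder-Mead on the log scale keeps every trial point in
    the valid parameter domain.  Default initial values: half the OLS
    residual variance for both tau2 and eta2, and 10% of the maximum
    pairwise distance for rho.  ``seed`` is accepted for interface symmetry;
    the optimisation itself is deterministic.

    Non-convergence is flagged (``converged=False``) and the best point found
    is returned rather than raising.
    """
    del seed
    ws = _BlockWorkspace(dataset, partition)
    if init is None:
        init = _default_init(dataset)
    init = np.asarray(init, dtype=float)
    if init.shape != (3,) or np.any(init <= 0):
        raise ValueError("init must be three positive values (tau2, eta2, rho)")
    options = {"xatol": 2e-3, "fatol": 5e-3, "maxiter": 400, "maxfev": 400}
    plateau = {"iters": 40, "rtol": 1e-6}
    if optimizer_settings:
        optimizer_settings = dict(optimizer_settings)
        plateau["iters"] = optimizer_settings.pop("plateau_iters", plateau["iters"])
        plateau["rtol"] = optimizer_settings.pop("plateau_rtol", plateau["rtol"])
        options.update(optimizer_settings)

    fam = family
    n_eval = 0
    history: list[float] = []

    def objective(log_theta: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        log_theta = np.clip(log_theta, -_LOG_CLIP, _LOG_CLIP)
        spec = CovarianceSpec(fam, *np.exp(log_theta))
        value = _objective_ws(ws, spec)
        if value is None:
            value = _penalty(log_theta)
        best = history[-1] if history else np.inf
        history.append(min(best, value))
        return value

    def plateau_stop(xk: np.ndarray) -> None:
        # when a fitted nugget or range runs to its boundary the simplex can
        # take many shrink steps after the objective has stopped moving; cut
        # the search once the best value has been flat for a while
        k = plateau["iters"]
        if len(history) > k:
            drop = history[-k - 1] - history[-1]
            if drop <= plateau["rtol"] * (1.0 + abs(history[-1])):
                raise StopIteration

    result = minimize(
        objective,
        np.log(init),
        method="Nelder-Mead",
        options=options,
        callback=plateau_stop,
    )
    theta = np.exp(np.clip(result.x, -_LOG_CLIP, _LOG_CLIP))
    spec = CovarianceSpec(fam, *theta)
    converged = bool(result.success) or result.status == 99  # 99: callback stop
    if not converged:
        logger.warning("blocked REML did not converge: %s", result.message)
    return _finalize_fit(ws, spec, float(result.fun), converged, n_eval)


def fit_fixed_effects(
    dataset: SpatialDataset,
    partition: PartitionIndex,
    spec_or_fit: CovarianceSpec | BlockedFit,
) -> BlockedFit:
    """Pooled fixed-effects estimate ``beta_bd = T_xx^{-1} t_xy`` at a given
    theta-hat, on a partition that may differ from the REML partition.

    When handed the REML fit together with its own partition object, the
    cached block inverses are reused as-is.
    """
    if isinstance(spec_or_fit, BlockedFit):
        if spec_or_fit.partition is partition and spec_or_fit.dataset is dataset:
            return spec_or_fit
        spec = spec_or_fit.spec
        converged = spec_or_fit.converged
    else:
        spec = spec_or_fit
        converged = True
    ws = _BlockWorkspace(dataset, partition)
    return _finalize_fit(ws, spec, objective=None, converged=converged)


@dataclass
class FixedEffectsResult:
    """Pooled fixed effects with an estimated covariance matrix."""

    beta: np.ndarray
    cov: np.ndarray
    estimator: str
    n_blocks_used: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.se > 0, self.beta / self.se, 0.0)

    @property
    def p(self) -> np.ndarray:
        p = 2.0 * (1.0 - ndtr(np.abs(self.z)))
        return np.where(self.se > 0, p, np.nan)

    def interval90(self) -> tuple[np.ndarray, np.ndarray]:
        half = 1.645 * self.se
        return self.beta - half, self.beta + half


def var_beta_exact(fit: BlockedFit, pair_chunk: int = 256) -> FixedEffectsResult:
    """Exact covariance of beta_bd under the full covariance matrix.

    Evaluates ``T_xx^{-1} + T_xx^{-1} W_xx T_xx^{-1}`` with the cross-block
    double sum accumulated pair by pair; each cross-covariance block V_ij is
    built on the fly and discarded, so peak extra storage is one chunk of
    pair blocks plus the R x R accumulator.
    """
    ws, g, spec = fit._ws, fit._G, fit.spec
    r = ws.R
    w_xx = np.zeros((r, r))
    if ws.P > 1:
        # padded rows of G are exactly zero, so no masking of V_ij is needed
        sq = np.einsum("psk,psk->ps", ws.coords, ws.coords)
        iu, ju = np.triu_indices(ws.P, k=1)
        for start in range(0, iu.size, pair_chunk):
            ic = iu[start : start + pair_chunk]
            jc = ju[start : start + pair_chunk]
            cross = ws.coords[ic] @ np.swapaxes(ws.coords[jc], 1, 2)
            d2 = sq[ic][:, :, None] + sq[jc][:, None, :] - 2.0 * cross
            d = np.sqrt(np.clip(d2, 0.0, None))
            v_ij = np.asarray(family_values(d, spec), dtype=float)
            tmp = v_ij @ g[jc]
            w_xx += np.tensordot(g[ic], tmp, axes=([0, 1], [0, 1]))
        w_xx = w_xx + w_xx.T
    t_inv = fit.Txx_inv
    cov = t_inv + t_inv @ w_xx @ t_inv
    cov = (cov + cov.T) / 2.0
    return FixedEffectsResult(fit.beta_bd.copy(), cov, "exact", ws.P)


def var_beta_empirical(fit: BlockedFit) -> FixedEffectsResult:
    """Empirical covariance from the spread of per-block GLS estimates:
    ``sum_i (beta_i - beta_bd)(beta_i - beta_bd)' / (P (P - 1))``.

    Blocks with a rank-deficient design are dropped (with a logged warning);
    at least two usable blocks are required.
    """
    betas, valid = fit.per_block_betas()
    if not valid.all():
        logger.warning(
            "empirical variance: dropped %d rank-deficient block(s)", int((~valid).sum())
        )
    betas = betas[valid]
    p = betas.shape[0]
    if p < 2:
        raise ValueError("empirical variance of beta_bd requires at least 2 usable blocks")
    dev = betas - fit.beta_bd
    cov = dev.T @ dev / (p * (p - 1))
    return FixedEffectsResult(fit.beta_bd.copy(), (cov + cov.T) / 2.0, "empirical", p)


def var_beta_pooled(fit: BlockedFit) -> FixedEffectsResult:
    """Pooled covariance ``sum_i (X_i' V_ii^{-1} X_i)^{-1} / P^2``.

    Singular block information matrices are skipped with P adjusted.
    """
    info = fit.block_information()
    total = np.zeros_like(info[0])
    used = 0
    for b in range(info.shape[0]):
        try:
            np.linalg.cholesky(info[b])
            total += np.linalg.inv(info[b])
            used += 1
        except np.linalg.LinAlgError:
            logger.warning("pooled variance: skipping singular block %d", b)
    if used == 0:
        raise ValueError("no usable blocks for the pooled variance estimator")
    cov = total / used**2
    return FixedEffectsResult(fit.beta_bd.copy(), (cov + cov.T) / 2.0, "pooled", used)


_VAR_ESTIMATORS = {
    "exact": var_beta_exact,
    "empirical": var_beta_empirical,
    "pooled": var_beta_pooled,
}


def estimate_var_beta(fit: BlockedFit, estimator: str = "exact") -> FixedEffectsResult:
    """Dispatch to one of the three variance estimators by name."""
    try:
        func = _VAR_ESTIMATORS[estimator]
    except KeyError:
        raise ValueError(f"unknown variance estimator {estimator!r}") from None
    return func(fit)


def wald_table(result: FixedEffectsResult, names: Sequence[str] | None = None) -> pd.DataFrame:
    """Wald-type fixed-effects table: estimate, standard error, z and the
    two-sided p-value against a standard normal reference."""
    r = result.beta.shape[0]
    if names is None:
        names = [f"beta_{j}" for j in range(r)]
    return pd.DataFrame(
        {
            "estimate": result.beta,
            "se": result.se,
            "z": np.where(result.se > 0, result.z, np.nan),
            "p": result.p,
        },
        index=list(names),
    )
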