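"""Block kriging: predict the average of the surface over a region.

The regional average ``Y(B) = |B|^{-1} int_B Y(s) ds`` is approximated by the
average of the field over a dense regular grid D inside B.  The block
predictor is the uniformly weighted mean of the nearest-neighbor global-beta
point predictions on that grid; being linear in the data, it can be written
``Yhat_D = a*' y_o`` with a single weight vector a* over the n observations.

Its exact prediction variance under the full covariance model is

    a*' V_oo a* - 2 a*' V_ou a + a' V_uu a,

with V_oo, V_ou, V_uu the observed/observed, observed/grid and grid/grid
covariance blocks and a the uniform grid weights.  The quadratic forms are
accumulated one row chunk at a time, so no n x n matrix is ever held in
memory.  For very large n an optional simple-random subsample of the
observations (with a Horvitz-Thompson correction for the quadratic form)
bounds the cost of the a*' V_oo a* term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .covariance import diag_value, family_values
from .estimate import BlockedFit, SpatialDataset
from .predict import _local_cov, find_neighbors

__all__ = [
    "BlockRegion",
    "BlockPredictionResult",
    "make_grid",
    "block_predict",
    "block_variance",
]


@dataclass(frozen=True)
class BlockRegion:
    """Dense grid approximation of a compact prediction region."""

    grid_points: np.ndarray
    weights: np.ndarray
    bounds: tuple[float, float, float, float]

    @property
    def n_grid(self) -> int:
        return self.grid_points.shape[0]


@dataclass
class BlockPredictionResult:
    prediction: float
    se: float | None
    n_grid: int
    m: int
    a_star: np.ndarray

    def interval90(self) -> tuple[float, float]:
        if self.se is None:
            raise ValueError("block variance has not been computed")
        half = 1.645 * self.se
        return self.prediction - half, self.prediction + half


def make_grid(bounds, resolution: int) -> BlockRegion:
    """Uniformly spaced resolution x resolution grid of cell centres.

    Row-major ordering (x varies fastest), uniform weights 1/resolution**2.
    """
    x0, x1, y0, y1 = (float(b) for b in bounds)
    if not (x1 > x0 and y1 > y0):
        raise ValueError(f"degenerate region bounds {bounds!r}")
    if resolution < 1:
        raise ValueError("resolution must be at least 1")
    xs = x0 + (np.arange(resolution) + 0.5) * (x1 - x0) / resolution
    ys = y0 + (np.arange(resolution) + 0.5) * (y1 - y0) / resolution
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel()])
    weights = np.full(points.shape[0], 1.0 / points.shape[0])
    return BlockRegion(points, weights, (x0, x1, y0, y1))


def block_predict(
    dataset: SpatialDataset,
    fit: BlockedFit,
    region: BlockRegion,
    pred_X_grid,
    m: int,
    C_hat,
    chunk: int = 512,
) -> BlockPredictionResult:
    """Block prediction as the weighted mean of global-beta point predictions.

    Also assembles the equivalent observation-weight vector a* (the mean of
    the per-site kriging weight vectors), which ``block_variance`` consumes.
    ``C_hat`` is accepted for interface consistency with point prediction;
    the block predictor itself does not depend on it.
    """
    del C_hat
    grid = region.grid_points
    pred_x = np.atleast_2d(np.asarray(pred_X_grid, dtype=float))
    w = region.weights
    spec, beta = fit.spec, fit.beta_bd
    nbrs = find_neighbors(dataset.coords, grid, m)
    n_sites = grid.shape[0]
    a_nb = np.zeros(dataset.n)
    dbar = np.zeros(dataset.n_covariates)
    total = 0.0
    for start in range(0, n_sites, chunk):
        sl = slice(start, min(start + chunk, n_sites))
        ii, v, c = _local_cov(dataset, nbrs, spec, sl)
        u = np.linalg.solve(v, c[..., None])[..., 0]
        px = dataset.X[ii]
        resid = dataset.y[ii] - px @ beta
        preds = pred_x[sl] @ beta + np.einsum("cm,cm->c", u, resid)
        total += float(w[sl] @ preds)
        np.add.at(a_nb, ii.ravel(), (u * w[sl, None]).ravel())
        dbar += w[sl] @ (pred_x[sl] - np.einsum("cmr,cm->cr", px, u))
    a_star = a_nb + fit.q_transpose() @ dbar
    return BlockPredictionResult(
        prediction=total, se=None, n_grid=n_sites, m=m, a_star=a_star
    )


def _cov_rows(coords_a, coords_b, spec, same_indices=None):
    """Chunk of covariance rows; nugget only where a row/column pair is the
    same observation (same_indices gives the global indices of the rows)."""
    v = np.asarray(family_values(cdist(coords_a, coords_b), spec), dtype=float)
    if same_indices is not None:
        v[np.arange(len(same_indices)), same_indices] += spec.eta2
    return v


def block_variance(
    dataset: SpatialDataset,
    fit: BlockedFit,
    region: BlockRegion,
    a_star: np.ndarray,
    subsample_cap: int | None = 5000,
    seed: int | None = None,
    chunk: int = 512,
) -> float:
    """Exact (streaming) block prediction variance.

    When ``subsample_cap`` is set and n exceeds it, the observed-data
    quadratic form is estimated from a seeded simple random sample of
    observations using Horvitz-Thompson inclusion weights; the grid terms
    are always exact.
    """
    a_star = np.asarray(a_star, dtype=float)
    spec = fit.spec
    obs = dataset.coords
    grid = region.grid_points
    a = region.weights
    n = obs.shape[0]

    if subsample_cap is not None and n > subsample_cap:
        rng = np.random.default_rng(seed)
        sel = np.sort(rng.choice(n, size=subsample_cap, replace=False))
        f1 = subsample_cap / n
        f2 = subsample_cap * (subsample_cap - 1) / (n * (n - 1))
    else:
        sel = np.arange(n)
        f1 = f2 = 1.0

    obs_s = obs[sel]
    a_s = a_star[sel]
    quad = 0.0
    diag_term = float(a_s @ a_s) * diag_value(spec)
    cross_oa = 0.0
    for start in range(0, sel.size, chunk):
        rows = slice(start, min(start + chunk, sel.size))
        v_oo = _cov_rows(obs_s[rows], obs_s, spec)
        quad += float(a_s[rows] @ (v_oo @ a_s))
        v_ou = _cov_rows(obs_s[rows], grid, spec)
        cross_oa += float(a_s[rows] @ (v_ou @ a))
    # quad included family(0) (no nugget) on its diagonal; swap in the full
    # diagonal value and apply the HT weights separately to diagonal and
    # off-diagonal parts
    fam0 = float(np.asarray(family_values(0.0, spec)))
    off_diag = quad - float(a_s @ a_s) * fam0
    term1 = diag_term / f1 + off_diag / f2
    term2 = cross_oa / f1

    term3 = 0.0
    for start in range(0, grid.shape[0], chunk):
        rows = slice(start, min(start + chunk, grid.shape[0]))
        v_uu = _cov_rows(
            grid[rows], grid, spec, same_indices=np.arange(rows.start, rows.stop)
        )
        term3 += float(a[rows] @ (v_uu @ a))

    var = term1 - 2.0 * term2 + term3
    return float(max(var, 0.0))
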