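"""Nearest-neighbor point prediction (universal kriging on local data).

Two predictors are offered for a site s_j with neighborhood data y_j
(the m nearest observations), local design X_j, local covariance V_j and
cross-covariance c_j:

global-beta (recommended)
    ``Yhat(s_j) = x_j' beta_bd + c_j' V_j^{-1} (y_j - X_j beta_bd)`` with the
    single pooled estimate beta_bd, keeping one coherent model across all
    prediction sites.  Its prediction variance

        sigma2 - c_j' V_j^{-1} c_j + d_j' C d_j,
        d_j = x_j - X_j' V_j^{-1} c_j,

    propagates the uncertainty of beta_bd through any estimate C of
    var(beta_bd).  By default sigma2 = tau2 + eta2, i.e. the interval targets
    a new noisy observation; pass ``target="surface"`` to predict the
    noise-free surface instead.

local-beta
    ordinary universal kriging computed entirely from the m neighbors,
    implicitly refitting beta in every neighborhood (a varying-coefficient
    model).  Columns of the local design that are identically zero in a
    neighborhood (e.g. an absent categorical level) are collapsed before
    solving.

Neighborhoods are exact Euclidean k-nearest-neighbor sets, recomputed per
site, with ties broken by the lowest observation index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .covariance import CovarianceSpec, diag_value, family_values
from .estimate import BlockedFit, FixedEffectsResult, SpatialDataset

__all__ = [
    "NeighborSet",
    "PredictionResult",
    "find_neighbors",
    "point_predict_global",
    "point_predict_local",
    "lambda_weights",
]


@dataclass(frozen=True)
class NeighborSet:
    """Nearest-neighbor indices and distances, one row per prediction site,
    sorted by ascending distance (ties by ascending index)."""

    indices: np.ndarray
    distances: np.ndarray

    @property
    def m(self) -> int:
        return self.indices.shape[1]


@dataclass
class PredictionResult:
    predictions: np.ndarray
    pred_se: np.ndarray
    mode: str
    m: int

    def interval90(self) -> tuple[np.ndarray, np.ndarray]:
        half = 1.645 * self.pred_se
        return self.predictions - half, self.predictions + half


def find_neighbors(obs_coords, pred_coords, m: int) -> NeighborSet:
    """Exact m-nearest-neighbor sets under Euclidean distance."""
    obs = np.atleast_2d(np.asarray(obs_coords, dtype=float))
    pred = np.atleast_2d(np.asarray(pred_coords, dtype=float))
    n = obs.shape[0]
    if not 1 <= m <= n:
        raise ValueError(f"neighbor count m={m} must be in [1, {n}]")
    tree = cKDTree(obs)
    k2 = min(n, m + 8)
    dist, idx = tree.query(pred, k=k2)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    # deterministic tie-break: re-sort rows containing tied distances by
    # (distance, index); fall back to brute force if a tie straddles the
    # query horizon
    tied = (np.diff(dist, axis=1) == 0).any(axis=1)
    for j in np.flatnonzero(tied):
        order = np.lexsort((idx[j], dist[j]))
        idx[j], dist[j] = idx[j][order], dist[j][order]
        if k2 < n and dist[j, m - 1] == dist[j, k2 - 1]:
            full = np.linalg.norm(obs - pred[j], axis=1)
            order = np.lexsort((np.arange(n), full))[:k2]
            idx[j], dist[j] = order, full[order]
    return NeighborSet(idx[:, :m].astype(np.intp), dist[:, :m])


def _local_cov(dataset: SpatialDataset, nbrs: NeighborSet, spec: CovarianceSpec, sl: slice):
    """Padded local covariance matrices and cross-covariance vectors for a
    chunk of prediction sites."""
    ii = nbrs.indices[sl]
    pc = dataset.coords[ii]
    diff = pc[:, :, None, :] - pc[:, None, :, :]
    d = np.sqrt(np.einsum("cijk,cijk->cij", diff, diff))
    v = np.asarray(family_values(d, spec), dtype=float)
    di = np.arange(ii.shape[1])
    v[:, di, di] = diag_value(spec)
    c = np.asarray(family_values(nbrs.distances[sl], spec), dtype=float)
    return ii, v, c


def _coerce_chat(c_hat) -> np.ndarray:
    if isinstance(c_hat, FixedEffectsResult):
        return c_hat.cov
    return np.asarray(c_hat, dtype=float)


def _safe_se(var: np.ndarray, scale: float) -> np.ndarray:
    if np.any(var < -1e-6 * max(scale, 1.0)):
        raise FloatingPointError("prediction variance came out substantially negative")
    return np.sqrt(np.clip(var, 0.0, None))


def point_predict_global(
    dataset: SpatialDataset,
    fit: BlockedFit,
    pred_coords,
    pred_X,
    m: int,
    C_hat,
    target: str = "observation",
    chunk: int = 512,
) -> PredictionResult:
    """Nearest-neighbor kriging with the single global beta_bd.

    ``C_hat`` is the estimated covariance of beta_bd (a FixedEffectsResult
    or an R x R matrix) used in the third variance term.
    """
    pred_coords = np.atleast_2d(np.asarray(pred_coords, dtype=float))
    pred_x = np.atleast_2d(np.asarray(pred_X, dtype=float))
    spec, beta = fit.spec, fit.beta_bd
    cmat = _coerce_chat(C_hat)
    sigma2 = diag_value(spec) - (spec.eta2 if target == "surface" else 0.0)
    nbrs = find_neighbors(dataset.coords, pred_coords, m)
    n_sites = pred_coords.shape[0]
    preds = np.empty(n_sites)
    variances = np.empty(n_sites)
    for start in range(0, n_sites, chunk):
        sl = slice(start, min(start + chunk, n_sites))
        ii, v, c = _local_cov(dataset, nbrs, spec, sl)
        try:
            u = np.linalg.solve(v, c[..., None])[..., 0]
        except np.linalg.LinAlgError:
            bad = _find_singular_site(v, start)
            raise np.linalg.LinAlgError(
                f"singular local covariance matrix at prediction site {bad}"
            ) from None
        px = dataset.X[ii]
        resid = dataset.y[ii] - px @ beta
        preds[sl] = pred_x[sl] @ beta + np.einsum("cm,cm->c", u, resid)
        dvec = pred_x[sl] - np.einsum("cmr,cm->cr", px, u)
        variances[sl] = (
            sigma2
            - np.einsum("cm,cm->c", c, u)
            + np.einsum("ci,ij,cj->c", dvec, cmat, dvec)
        )
    return PredictionResult(preds, _safe_se(variances, sigma2), "global_beta", m)


def _find_singular_site(v: np.ndarray, offset: int) -> int:
    for k in range(v.shape[0]):
        try:
            np.linalg.cholesky(v[k])
        except np.linalg.LinAlgError:
            return offset + k
    return offset


def point_predict_local(
    dataset: SpatialDataset,
    theta_or_fit,
    pred_coords,
    pred_X,
    m: int,
    target: str = "observation",
    chunk: int = 512,
) -> PredictionResult:
    """Purely local universal kriging: beta is re-estimated by GLS from each
    neighborhood (empirical BLUE/BLUP on the m neighbors only).

    All-zero columns of a local design are collapsed; if the design is still
    rank deficient the offending columns are reported.
    """
    pred_coords = np.atleast_2d(np.asarray(pred_coords, dtype=float))
    pred_x = np.atleast_2d(np.asarray(pred_X, dtype=float))
    spec = theta_or_fit.spec if isinstance(theta_or_fit, BlockedFit) else theta_or_fit
    sigma2 = diag_value(spec) - (spec.eta2 if target == "surface" else 0.0)
    nbrs = find_neighbors(dataset.coords, pred_coords, m)
    n_sites = pred_coords.shape[0]
    preds = np.empty(n_sites)
    variances = np.empty(n_sites)
    for start in range(0, n_sites, chunk):
        sl = slice(start, min(start + chunk, n_sites))
        ii, v, c = _local_cov(dataset, nbrs, spec, sl)
        px = dataset.X[ii]
        py = dataset.y[ii]
        zero_cols = (np.abs(px).max(axis=1) == 0.0).any(axis=1)
        easy = ~zero_cols
        if easy.any():
            sol = np.linalg.solve(v[easy], np.concatenate([px[easy], c[easy][..., None]], axis=2))
            vinv_x, u = sol[:, :, :-1], sol[:, :, -1]
            info = np.einsum("cmi,cmj->cij", px[easy], vinv_x)
            try:
                np.linalg.cholesky(info)
            except np.linalg.LinAlgError:
                # rare: rank deficiency without an all-zero column; recompute
                # those sites one at a time below
                easy[:] = False
            if easy.any():
                bxy = np.einsum("cmi,cm->ci", vinv_x, py[easy])
                bloc = np.linalg.solve(info, bxy[..., None])[..., 0]
                resid = py[easy] - np.einsum("cmi,ci->cm", px[easy], bloc)
                pe = np.einsum("ci,ci->c", pred_x[sl][easy], bloc) + np.einsum(
                    "cm,cm->c", u, resid
                )
                dvec = pred_x[sl][easy] - np.einsum("cmr,cm->cr", px[easy], u)
                quad = np.einsum("ci,ci->c", dvec, np.linalg.solve(info, dvec[..., None])[..., 0])
                ve = sigma2 - np.einsum("cm,cm->c", c, u) + quad
                out_idx = np.flatnonzero(easy) + start
                preds[out_idx], variances[out_idx] = pe, ve
        for k in np.flatnonzero(~easy):
            j = start + k
            preds[j], variances[j] = _local_one_site(
                v[k], px[k], py[k], c[k], pred_x[j], sigma2, j
            )
    return PredictionResult(preds, _safe_se(variances, sigma2), "local_beta", m)


def _local_one_site(v, px, py, c, xj, sigma2, site) -> tuple[float, float]:
    keep = np.flatnonzero(np.abs(px).max(axis=0) > 0.0)
    xk = px[:, keep]
    if np.linalg.matrix_rank(xk) < keep.size:
        # report in terms of the original column numbering
        raise np.linalg.LinAlgError(
            f"local design at prediction site {site} is rank deficient even "
            f"after collapsing all-zero columns; columns {keep.tolist()}"
        )
    sol = np.linalg.solve(v, np.column_stack([xk, c, py]))
    vinv_x, u, vinv_y = sol[:, : keep.size], sol[:, keep.size], sol[:, keep.size + 1]
    info = xk.T @ vinv_x
    bloc = np.linalg.solve(info, xk.T @ vinv_y)
    pred = float(xj[keep] @ bloc + u @ (py - xk @ bloc))
    d = xj[keep] - xk.T @ u
    var = float(sigma2 - c @ u + d @ np.linalg.solve(info, d))
    return pred, var


def lambda_weights(
    dataset: SpatialDataset,
    fit: BlockedFit,
    site_coords,
    site_x,
    m: int,
) -> np.ndarray:
    """Kriging weights of the global-beta predictor over all n observations.

    The predictor is linear in y: ``Yhat(s_j) = lambda_j' y`` with

        lambda_j = N_j' V_j^{-1} c_j + Q' (x_j - X_j' V_j^{-1} c_j)

    where N_j subsets y to the neighborhood and Q is the pooled-estimator
    matrix.  The weights reproduce ``point_predict_global`` exactly and
    satisfy the unbiasedness identity ``lambda_j' X = x_j'``.
    """
    site_coords = np.asarray(site_coords, dtype=float).reshape(1, 2)
    site_x = np.asarray(site_x, dtype=float).ravel()
    spec = fit.spec
    nbrs = find_neighbors(dataset.coords, site_coords, m)
    ii, v, c = _local_cov(dataset, nbrs, spec, slice(0, 1))
    u = np.linalg.solve(v[0], c[0])
    lam = np.zeros(dataset.n)
    lam[ii[0]] = u
    d = site_x - dataset.X[ii[0]].T @ u
    lam += fit.q_transpose() @ d
    return lam
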