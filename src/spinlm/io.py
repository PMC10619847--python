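"""CSV/JSON readers and writers for datasets, fits and predictions."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .covariance import CovarianceSpec
from .estimate import BlockedFit, FixedEffectsResult, SpatialDataset, fit_fixed_effects
from .partition import PartitionIndex
from .predict import PredictionResult

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_fit",
    "read_fit",
    "write_predictions",
]

logger = logging.getLogger(__name__)


def read_dataset(
    path,
    coord_cols: tuple[str, str] = ("x", "y"),
    response_col: str | None = "response",
    covariate_cols: tuple[str, ...] = (),
    add_intercept: bool = True,
) -> SpatialDataset:
    """Load a point-referenced dataset from a CSV file with a header row.

    ``response_col=None`` reads prediction sites (the response is filled
    with zeros).  Rows with missing values in any used column are rejected
    with their row numbers; extra columns are ignored with a notice.
    """
    frame = pd.read_csv(path)
    if frame.columns.duplicated().any():
        dupes = frame.columns[frame.columns.duplicated()].tolist()
        raise ValueError(f"duplicate column names in {path}: {dupes}")
    used = list(coord_cols) + list(covariate_cols)
    if response_col is not None:
        used.append(response_col)
    missing = [c for c in used if c not in frame.columns]
    if missing:
        raise ValueError(f"missing columns in {path}: {missing}")
    unused = [c for c in frame.columns if c not in used]
    if unused:
        logger.info("ignoring unused columns in %s: %s", path, unused)
    sub = frame[used]
    bad = sub.isna().any(axis=1)
    if bad.any():
        rows = (np.flatnonzero(bad) + 2).tolist()  # 1-based, after the header
        raise ValueError(f"missing values in {path} at file rows {rows}")
    try:
        values = sub.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cells in {path}: {exc}") from None
    coords = values[:, :2]
    ncov = len(covariate_cols)
    covs = values[:, 2 : 2 + ncov]
    x = np.column_stack([np.ones(len(frame)), covs]) if add_intercept else covs
    if x.shape[1] == 0:
        x = np.ones((len(frame), 1))
    y = values[:, -1] if response_col is not None else np.zeros(len(frame))
    return SpatialDataset(coords, x, y)


def write_dataset(dataset: SpatialDataset, path, covariate_names=None) -> None:
    """Write a dataset back to CSV (coordinates, covariates sans intercept,
    response)."""
    r = dataset.n_covariates
    if covariate_names is None:
        covariate_names = [f"x{j}" for j in range(1, r)]
    frame = pd.DataFrame({"x": dataset.coords[:, 0], "y": dataset.coords[:, 1]})
    for j, name in enumerate(covariate_names, start=1):
        frame[name] = dataset.X[:, j]
    frame["response"] = dataset.y
    frame.to_csv(path, index=False)


def write_fit(
    fit: BlockedFit,
    path,
    C_hat: FixedEffectsResult | None = None,
    config: dict | None = None,
) -> None:
    """Serialise a fit as JSON: theta-hat, beta, optional covariance of beta,
    partition labels and a config echo."""
    spec = fit.spec
    family = spec.family if isinstance(spec.family, str) else "user"
    payload = {
        "family": family,
        "theta": {"tau2": spec.tau2, "eta2": spec.eta2, "rho": spec.rho},
        "beta": fit.beta_bd.tolist(),
        "objective": fit.objective,
        "converged": fit.converged,
        "partition": {
            "labels": fit.partition.labels.tolist(),
            "method": fit.partition.method,
            "target_size": fit.partition.target_size,
        },
        "config": config or {},
    }
    if C_hat is not None:
        payload["C_hat"] = np.asarray(_cov_of(C_hat)).tolist()
        if isinstance(C_hat, FixedEffectsResult):
            payload["var_estimator"] = C_hat.estimator
    Path(path).write_text(json.dumps(payload, indent=1))


def _cov_of(c_hat):
    return c_hat.cov if isinstance(c_hat, FixedEffectsResult) else c_hat


def read_fit(path, dataset: SpatialDataset):
    """Rebuild a BlockedFit (with its caches) from a JSON file plus the
    dataset it was fitted to.  Returns (fit, C_hat or None, config echo)."""
    payload = json.loads(Path(path).read_text())
    if payload["family"] == "user":
        raise ValueError("fits with user-supplied covariance families cannot be reloaded")
    spec = CovarianceSpec(payload["family"], **payload["theta"])
    part = payload["partition"]
    labels = np.asarray(part["labels"], dtype=np.intp)
    partition = PartitionIndex(
        labels, int(labels.max()) + 1, part["method"], int(part["target_size"])
    )
    fit = fit_fixed_effects(dataset, partition, spec)
    c_hat = np.asarray(payload["C_hat"], dtype=float) if "C_hat" in payload else None
    return fit, c_hat, payload.get("config", {})


def write_predictions(result: PredictionResult, coords, path) -> None:
    """Predictions as CSV with 90% interval bounds (1.645 multiplier)."""
    coords = np.asarray(coords, dtype=float)
    lower, upper = result.interval90()
    pd.DataFrame(
        {
            "site": np.arange(len(result.predictions)),
            "x": coords[:, 0],
            "y": coords[:, 1],
            "prediction": result.predictions,
            "pred_se": result.pred_se,
            "lower90": lower,
            "upper90": upper,
        }
    ).to_csv(path, index=False)
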