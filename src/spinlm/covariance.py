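"""Stationary spatial covariance functions and covariance-matrix builders.

The covariance of the error process is parameterised by theta = (tau2, eta2,
rho): the partial sill (spatially structured variance), the nugget
(micro-scale / measurement-error variance) and the range (distance scale of
correlation decay).  Two classical isotropic families are built in:

exponential
    ``tau2 * exp(-d / rho)``, positive for every distance.
spherical
    ``tau2 * (1 - 3 d / (2 rho) + d**3 / (2 rho**3))`` for ``d < rho`` and
    exactly zero beyond the range.

A user-supplied family is accepted as a callable
``f(distance, (tau2, eta2, rho), on_diagonal) -> value`` that must be
vectorised over ``distance``; any construction that yields a valid
(positive-definite) covariance matrix can be plugged in this way.

Nugget placement: the nugget is added only on the true diagonal of a
same-point-set covariance matrix, i.e. it is treated as measurement error
attached to an individual observation.  Cross-covariance entries between
distinct observations -- or between data and prediction locations -- never
include the nugget, even at coincident coordinates.  This keeps the matrix
nonsingular under duplicated coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "CovarianceSpec",
    "NumericalDegeneracyError",
    "cov_exponential",
    "cov_spherical",
    "cov_value",
    "family_values",
    "build_cov_matrix",
]


class NumericalDegeneracyError(np.linalg.LinAlgError):
    """A covariance matrix failed its Cholesky factorization."""


FamilyLike = Union[str, Callable[..., np.ndarray]]


@dataclass(frozen=True)
class CovarianceSpec:
    """Covariance family plus parameter vector theta = (tau2, eta2, rho).

    Parameters
    ----------
    family:
        ``"exponential"``, ``"spherical"`` or a callable
        ``f(distance, params, on_diagonal)``.
    tau2:
        Partial sill, must be > 0 (variance units).
    eta2:
        Nugget, must be >= 0 (variance units).
    rho:
        Range, must be > 0 (distance units).
    """

    family: FamilyLike
    tau2: float
    eta2: float
    rho: float

    def __post_init__(self) -> None:
        if isinstance(self.family, str) and self.family not in ("exponential", "spherical"):
            raise ValueError(f"unknown covariance family {self.family!r}")
        if not (isinstance(self.family, str) or callable(self.family)):
            raise TypeError("family must be a name or a callable")
        for name in ("tau2", "eta2", "rho"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.tau2 <= 0:
            raise ValueError(f"partial sill tau2 must be > 0, got {self.tau2}")
        if self.eta2 < 0:
            raise ValueError(f"nugget eta2 must be >= 0, got {self.eta2}")
        if self.rho <= 0:
            raise ValueError(f"range rho must be > 0, got {self.rho}")

    @property
    def theta(self) -> tuple[float, float, float]:
        return (self.tau2, self.eta2, self.rho)

    @property
    def sigma2(self) -> float:
        """Stationary variance tau2 + eta2 (the function value at d = 0)."""
        return float(cov_value(0.0, self, on_diagonal=True))


def _check_distances(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    return d


def cov_exponential(d, spec: CovarianceSpec, on_diagonal: bool = False):
    """Exponential covariance ``tau2 * exp(-d/rho)``, plus the nugget iff
    ``on_diagonal``."""
    d = _check_distances(d)
    value = spec.tau2 * np.exp(-d / spec.rho)
    if on_diagonal:
        value = value + spec.eta2
    return value


def cov_spherical(d, spec: CovarianceSpec, on_diagonal: bool = False):
    """Spherical covariance with compact support: exactly zero for d >= rho
    (off the diagonal)."""
    d = _check_distances(d)
    h = d / spec.rho
    value = spec.tau2 * (1.0 - 1.5 * h + 0.5 * h**3) * (h < 1.0)
    if on_diagonal:
        value = value + spec.eta2
    return value


_BUILTIN = {"exponential": cov_exponential, "spherical": cov_spherical}


def cov_value(d, spec: CovarianceSpec, on_diagonal: bool = False):
    """Evaluate the covariance function of ``spec`` at distance(s) ``d``."""
    if callable(spec.family):
        return spec.family(_check_distances(d), spec.theta, on_diagonal)
    return _BUILTIN[spec.family](d, spec, on_diagonal)


def family_values(d, spec: CovarianceSpec):
    """Off-diagonal (nugget-free) covariance values, vectorised over ``d``."""
    return cov_value(d, spec, on_diagonal=False)


def diag_value(spec: CovarianceSpec) -> float:
    """Variance of a single observation: the function value at zero distance
    on the diagonal (tau2 + eta2 for the built-in families)."""
    return float(np.asarray(cov_value(0.0, spec, on_diagonal=True)))


def build_cov_matrix(
    coords_a: np.ndarray,
    spec: CovarianceSpec,
    coords_b: np.ndarray | None = None,
    check: bool = True,
) -> np.ndarray:
    """Covariance matrix between two point sets.

    With ``coords_b=None`` the same-set matrix is returned: the nugget is
    added on the diagonal and (by default) positive definiteness is verified
    with a Cholesky factorization.  Otherwise the cross-covariance matrix is
    returned, which never includes the nugget.

    Raises
    ------
    NumericalDegeneracyError
        If the same-set matrix is not positive definite for these parameters.
    """
    coords_a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    if coords_a.ndim != 2 or coords_a.shape[0] == 0:
        raise ValueError("coordinates must be a non-empty 2-D array")
    if coords_b is None:
        dmat = cdist(coords_a, coords_a)
        v = np.asarray(family_values(dmat, spec), dtype=float)
        np.fill_diagonal(v, diag_value(spec))
        if check:
            try:
                np.linalg.cholesky(v)
            except np.linalg.LinAlgError as exc:
                raise NumericalDegeneracyError(
                    "covariance matrix is not positive definite for "
                    f"tau2={spec.tau2:g}, eta2={spec.eta2:g}, rho={spec.rho:g}"
                ) from exc
        return v
    coords_b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if coords_b.ndim != 2 or coords_b.shape[0] == 0:
        raise ValueError("coordinates must be a non-empty 2-D array")
    dmat = cdist(coords_a, coords_b)
    return np.asarray(family_values(dmat, spec), dtype=float)
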