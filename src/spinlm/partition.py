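"""Partitioning (spatial indexing) of observations into blocks.

Blocked estimation treats the covariance matrix as block diagonal along a
partition of the observations.  Three schemes are provided:

``partition_random`` (RAND)
    uniformly random assignment, block sizes equal up to one;
``partition_compact`` (COMP)
    k-means clustering of the spatial coordinates, giving spatially
    contiguous blocks (sizes vary with the point pattern);
``partition_mixed`` (MIXD)
    compact blocks with a fraction of each block reassigned at random to
    another block.

The number of blocks is always ``P = ceil(n / target_size)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "PartitionIndex",
    "partition_random",
    "partition_compact",
    "partition_mixed",
]


@dataclass(frozen=True)
class PartitionIndex:
    """Block assignment of n observations to blocks 0 .. P-1."""

    labels: np.ndarray
    n_blocks: int
    method: str
    target_size: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.intp)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        sizes = np.bincount(labels, minlength=self.n_blocks)
        if len(sizes) != self.n_blocks or (sizes == 0).any():
            raise ValueError("every block must be non-empty")

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_blocks)

    def block_indices(self) -> list[np.ndarray]:
        order = np.argsort(self.labels, kind="stable")
        bounds = np.cumsum(self.sizes)[:-1]
        return np.split(order, bounds)


def _n_blocks(n: int, target_size: int) -> int:
    if target_size < 2:
        raise ValueError("target_size must be at least 2")
    if target_size > n:
        raise ValueError(f"target_size {target_size} exceeds sample size {n}")
    return math.ceil(n / target_size)


def _coerce_coords(coords) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2:
        raise ValueError("coords must be an (n, 2) array")
    return coords


def partition_random(coords, target_size: int, seed: int | None = None) -> PartitionIndex:
    """Uniformly random partition with block sizes differing by at most 1."""
    coords = _coerce_coords(coords)
    n = coords.shape[0]
    p = _n_blocks(n, target_size)
    rng = np.random.default_rng(seed)
    labels = np.empty(n, dtype=np.intp)
    labels[rng.permutation(n)] = np.arange(n) % p
    return PartitionIndex(labels, p, "rand", target_size)


def partition_compact(coords, target_size: int, seed: int | None = None) -> PartitionIndex:
    """Spatially compact partition from k-means on the raw coordinates.

    Lloyd iterations with k-means++ seeding; block sizes vary around the
    target because k-means balances within-cluster variance, not counts.
    """
    coords = _coerce_coords(coords)
    n = coords.shape[0]
    p = _n_blocks(n, target_size)
    if p == 1:
        labels = np.zeros(n, dtype=np.intp)
    else:
        state = None if seed is None else int(seed) % (2**32 - 1)
        km = KMeans(n_clusters=p, n_init="auto", random_state=state)
        labels = km.fit_predict(coords).astype(np.intp)
    return PartitionIndex(labels, p, "comp", target_size)


def partition_mixed(
    coords,
    target_size: int,
    frac_reassigned: float = 0.10,
    seed: int | None = None,
) -> PartitionIndex:
    """Compact partition with a fraction of each block randomly reassigned.

    From each compact block, ``floor(frac_reassigned * size)`` members are
    drawn at random and moved to a uniformly random other block.  If the
    reassignment empties a block, one of its moved members is put back so
    every block stays non-empty.
    """
    if not 0.0 <= frac_reassigned <= 1.0:
        raise ValueError("frac_reassigned must be in [0, 1]")
    base = partition_compact(coords, target_size, seed=seed)
    rng = np.random.default_rng(None if seed is None else [int(seed), 0x5EED])
    labels = base.labels.copy()
    p = base.n_blocks
    if p == 1 or frac_reassigned == 0.0:
        return PartitionIndex(labels, p, "mixd", target_size)
    moved_from: dict[int, list[int]] = {b: [] for b in range(p)}
    for b in range(p):
        members = np.flatnonzero(base.labels == b)
        k = int(math.floor(frac_reassigned * members.size))
        if k == 0:
            continue
        chosen = rng.choice(members, size=k, replace=False)
        # destination drawn uniformly among the other P-1 blocks
        dest = rng.integers(0, p - 1, size=k)
        dest = dest + (dest >= b)
        labels[chosen] = dest
        moved_from[b].extend(chosen.tolist())
    sizes = np.bincount(labels, minlength=p)
    for b in np.flatnonzero(sizes == 0):
        pool = [i for i in moved_from[b] if sizes[labels[i]] > 1]
        back = int(rng.choice(pool))
        sizes[labels[back]] -= 1
        labels[back] = b
        sizes[b] += 1
    return PartitionIndex(labels, p, "mixd", target_size)
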