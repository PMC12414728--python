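"""Bootstrap resampling of telemetry records with in-bag/out-of-bag bookkeeping.

Two schemes are provided. The iid scheme resamples record indices uniformly
with replacement. The blocked scheme partitions records into contiguous-in-time
blocks and resamples with replacement *within* each block (stratified
resampling), which respects serial dependence in telemetry data while keeping
per-block record counts exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BootstrapSample",
    "draw_iid",
    "partition_blocks",
    "draw_blocked",
    "default_n_blocks",
]

#: target records per block when n_blocks is not given
DEFAULT_BLOCK_SIZE = 20


@dataclass(frozen=True)
class BootstrapSample:
    """One bootstrap resample of ``n`` record indices.

    ``indices`` is a multiset (length n, repeats allowed) of row indices into
    a telemetry table; ``oob`` are the rows absent from ``indices``.
    """

    indices: np.ndarray
    oob: np.ndarray
    block_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=np.intp))
        object.__setattr__(self, "oob", np.asarray(self.oob, dtype=np.intp))

    @property
    def n(self) -> int:
        return int(self.indices.size)

    def oob_mask(self) -> np.ndarray:
        mask = np.zeros(self.n, dtype=bool)
        mask[self.oob] = True
        return mask


def _oob_from_indices(indices: np.ndarray, n: int) -> np.ndarray:
    in_bag = np.zeros(n, dtype=bool)
    in_bag[indices] = True
    return np.nonzero(~in_bag)[0]


def draw_iid(n: int, rng: np.random.Generator) -> BootstrapSample:
    """Draw n record indices uniformly with replacement from {0..n-1}."""
    if n < 1:
        raise ValueError("n must be at least 1")
    indices = rng.integers(0, n, size=n)
    return BootstrapSample(indices, _oob_from_indices(indices, n))


def partition_blocks(times: np.ndarray, n_blocks: int) -> np.ndarray:
    """Assign sorted records to contiguous-in-time blocks of near-equal size.

    Blocks are defined on record ranks (not elapsed time), so irregular
    sampling cannot create empty blocks. Sizes differ by at most one, with
    earlier blocks taking the remainder.
    """
    times = np.asarray(times, dtype=float)
    n = times.size
    if not (1 <= n_blocks <= n):
        raise ValueError(f"n_blocks must be in [1, {n}], got {n_blocks}")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted non-decreasing")
    base, rem = divmod(n, n_blocks)
    sizes = np.full(n_blocks, base, dtype=np.intp)
    sizes[:rem] += 1
    return np.repeat(np.arange(n_blocks, dtype=np.intp), sizes)


def default_n_blocks(n: int) -> int:
    """Default block count: target block size of ~20 records."""
    return max(1, n // DEFAULT_BLOCK_SIZE)


def draw_blocked(
    times: np.ndarray, n_blocks: int, rng: np.random.Generator
) -> BootstrapSample:
    """Stratified (within-block) bootstrap of sorted telemetry records.

    Within each contiguous time block, exactly that block's size of indices
    is drawn with replacement from the block; samples are concatenated in
    block order so in-bag times remain grouped by block.
    """
    times = np.asarray(times, dtype=float)
    n = times.size
    labels = partition_blocks(times, n_blocks)
    starts = np.searchsorted(labels, np.arange(n_blocks), side="left")
    ends = np.searchsorted(labels, np.arange(n_blocks), side="right")
    parts = [
        rng.integers(lo, hi, size=hi - lo) for lo, hi in zip(starts, ends)
    ]
    indices = np.concatenate(parts)
    return BootstrapSample(indices, _oob_from_indices(indices, n), block_labels=labels)
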