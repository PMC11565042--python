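"""Shared resampling machinery: subsampling, half-splits, percentile CIs.

All randomness flows from one master seed.  Per-(metric, condition, n)
substreams are derived deterministically with :func:`substream`, so adding a
grid point never perturbs the draws at other points.  Identical inputs and
seed give identical draws; cross-library bit-equality is not promised,
statistical equality is.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ResampleConfig",
    "ResampleSummary",
    "substream",
    "subsample_trials",
    "split_into_bins",
    "percentile_ci",
    "summarize_draws",
    "EXCLUDED",
]

# Sentinel returned by subsample_trials for a cell with fewer than n trials:
# the participant is dropped from that grid point (never padded or resampled
# with replacement, which would change the estimand).
EXCLUDED = None


@dataclass(frozen=True)
class ResampleConfig:
    """Iteration count, seed, subsample grid and CI level for resampling runs.

    Parameters
    ----------
    n_iterations
        Number of resampling iterations B (default 1000; typical range
        1000-5000).
    seed
        Master seed; every substream derives from it.
    grid
        Strictly increasing subsample sizes, each >= 2 (a split needs two
        non-empty bins).  Empty grid means overall-only runs.
    ci_level
        Two-sided percentile-interval coverage, default 0.95.
    retain_draws
        Keep the per-iteration estimates on each summary (for audit dumps).
    """

    n_iterations: int = 1000
    seed: int = 0
    grid: tuple[int, ...] = ()
    ci_level: float = 0.95
    retain_draws: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        grid = tuple(int(n) for n in self.grid)
        if any(n < 2 for n in grid):
            raise ValueError("grid entries must be >= 2")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("grid must be strictly increasing")
        object.__setattr__(self, "grid", grid)

    def with_seed(self, seed: int) -> "ResampleConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class ResampleSummary:
    """Mean and percentile CI of one iteration distribution.

    ``n_trials`` is None for overall-scope summaries.  ``draws`` holds the
    per-iteration estimates when the config asked for them.
    """

    n_trials: int | None
    n_iterations: int
    n_participants_used: int
    mean_estimate: float
    ci_low: float
    ci_high: float
    draws: np.ndarray | None = field(default=None, repr=False, compare=False)


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Derive a deterministic child RNG from a master seed and string keys.

    Keys are hashed (SHA-256, first 8 bytes) so the stream depends only on
    the key values, never on iteration order elsewhere.
    """
    words = [int(seed)]
    for k in keys:
        digest = hashlib.sha256(repr(k).encode()).digest()
        words.append(int.from_bytes(digest[:8], "little"))
    return np.random.default_rng(np.random.SeedSequence(words))


def subsample_trials(
    cell_values: np.ndarray | Sequence[float], n: int, rng: np.random.Generator
):
    """Draw n distinct trials uniformly without replacement from one cell.

    Returns :data:`EXCLUDED` when the cell has fewer than n trials — the
    participant is dropped from that subsample size.
    """
    if n <= 0:
        raise ValueError("subsample size n must be positive")
    values = np.asarray(cell_values, dtype=float)
    if values.size < n:
        return EXCLUDED
    idx = rng.permutation(values.size)[:n]
    return values[idx]


def split_into_bins(
    values: np.ndarray | Sequence[float], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly partition trial values into two near-equal bins.

    Bin sizes are floor(k/2) and ceil(k/2); the assignment is uniform over
    partitions of those sizes.
    """
    values = np.asarray(values, dtype=float)
    k = values.size
    if k < 2:
        raise ValueError("need at least 2 values to split into two bins")
    perm = rng.permutation(k)
    half = k // 2
    return values[perm[:half]], values[perm[half:]]


def percentile_ci(
    draws: np.ndarray | Sequence[float], level: float = 0.95
) -> tuple[float, float]:
    """Empirical percentile interval of an iteration distribution.

    Quantiles at (1-level)/2 and 1-(1-level)/2 with linear interpolation
    between order statistics: quantile q sits at fractional position
    1 + q*(B-1) in the sorted draws.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("draws must be non-empty")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def summarize_draws(
    draws: np.ndarray | Sequence[float],
    config: ResampleConfig,
    n_trials: int | None,
    n_participants: int,
) -> ResampleSummary:
    """Summarize per-iteration estimates into mean + percentile CI."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("draws must be non-empty")
    lo, hi = percentile_ci(draws, config.ci_level)
    return ResampleSummary(
        n_trials=n_trials,
        n_iterations=config.n_iterations,
        n_participants_used=n_participants,
        mean_estimate=float(draws.mean()),
        ci_low=lo,
        ci_high=hi,
        draws=draws.copy() if config.retain_draws else None,
    )
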