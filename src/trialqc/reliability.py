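"""Split-half internal-consistency reliability with Spearman-Brown correction.

One iteration: within each eligible participant, subsample n trials (or take
the full, possibly ragged, trial set for overall scope), randomly split them
into two near-equal bins, average each bin, then Pearson-correlate the two
per-participant bin-mean vectors across participants and correct the
half-length coefficient to full length with the Spearman-Brown formula

    r_full = 2 r_half / (1 + r_half).

Repeating B times (typically 1000-5000) yields a distribution of corrected
estimates whose mean and percentile CI are reported, overall and per
subsample size n — the reliability curve used to judge how many trials a
paradigm needs to reach the conventional thresholds (.60 acceptable,
.70-.80 good, .90 excellent).

Conventions (documented design choices):

* Pearson correlation between the half-mean vectors.
* At least 3 eligible participants (a correlation from 2 points is always
  +/-1, hence degenerate).
* Negative r_half passes through the correction unclamped; truncating at 0
  would bias the iteration mean.
* Iterations where either bin-mean vector has zero variance (or r_half = -1)
  have no defined estimate; they are dropped from the summary and counted in
  ``n_undefined``.
* Participants with fewer than n trials are excluded at that grid point;
  eligibility is fixed across iterations, so ``n_participants_used`` is
  constant for a given n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientSampleError
from .io import TrialTable
from .resample import (
    EXCLUDED,
    ResampleConfig,
    ResampleSummary,
    split_into_bins,
    subsample_trials,
    substream,
    summarize_draws,
)

__all__ = [
    "ReliabilityResult",
    "spearman_brown",
    "split_half_estimate",
    "reliability_overall",
    "reliability_curve",
]

log = logging.getLogger(__name__)

MIN_PARTICIPANTS = 3


@dataclass(frozen=True)
class ReliabilityResult:
    """Per-condition reliability summary for one scope (overall or one n)."""

    condition: str
    scope: str  # "overall" | "subsample"
    summary: ResampleSummary | None
    n_undefined: int = 0
    available: bool = True
    unavailable_reason: str | None = None

    def to_rows(self) -> list[dict]:
        if not self.available or self.summary is None:
            return []
        s = self.summary
        return [
            {
                "metric": "reliability",
                "condition": self.condition,
                "contrast": "",
                "scope": self.scope,
                "n_trials": s.n_trials,
                "n_iterations": s.n_iterations,
                "n_participants": s.n_participants_used,
                "estimate": s.mean_estimate,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
            }
        ]


def spearman_brown(r_half: float) -> float:
    """Correct a half-length reliability coefficient to full length.

    r_full = 2 r_half / (1 + r_half); monotone increasing on (-1, 1],
    fixing 0 and 1.  Undefined at r_half = -1.
    """
    if not -1.0 <= r_half <= 1.0:
        raise ValueError(f"r_half must lie in [-1, 1], got {r_half}")
    if r_half == -1.0:
        raise ZeroDivisionError("Spearman-Brown correction undefined at r_half = -1")
    return 2.0 * r_half / (1.0 + r_half)


def _corrected_split_half(cells: list[np.ndarray], n: int | None,
                          rng: np.random.Generator) -> float:
    """One iteration's corrected estimate over pre-collected eligible cells.

    Returns NaN when the correlation is undefined for this iteration.
    """
    k = len(cells)
    a = np.empty(k)
    b = np.empty(k)
    for i, vals in enumerate(cells):
        sel = vals if n is None else subsample_trials(vals, n, rng)
        bin_a, bin_b = split_into_bins(sel, rng)
        a[i] = bin_a.mean()
        b[i] = bin_b.mean()
    sa = a.std()
    sb = b.std()
    if sa == 0.0 or sb == 0.0:
        return np.nan
    r = float(np.dot(a - a.mean(), b - b.mean()) / (k * sa * sb))
    r = min(1.0, max(-1.0, r))  # clip float round-off
    if r == -1.0:
        return np.nan
    return spearman_brown(r)


def _eligible_cells(
    table: TrialTable, condition: str, min_trials: int
) -> tuple[list[str], list[np.ndarray]]:
    ids, cells = [], []
    for pid, vals in table.cells(condition).items():
        if vals.size >= min_trials:
            ids.append(pid)
            cells.append(vals)
    return ids, cells


def split_half_estimate(
    table: TrialTable,
    condition: str,
    rng: np.random.Generator,
    n: int | None = None,
) -> float:
    """One corrected split-half estimate (single iteration).

    ``n=None`` means overall scope: each participant contributes their full
    (possibly ragged) trial set.  Returns NaN when the correlation is
    undefined for this iteration.
    """
    min_trials = 2 if n is None else n
    ids, cells = _eligible_cells(table, condition, min_trials)
    if len(cells) < MIN_PARTICIPANTS:
        raise InsufficientSampleError(
            f"condition {condition!r}: {len(cells)} eligible participants "
            f"(need >= {MIN_PARTICIPANTS}) at n={'all' if n is None else n}"
        )
    return _corrected_split_half(cells, n, rng)


def _run_iterations(
    cells: list[np.ndarray],
    n: int | None,
    config: ResampleConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    draws = np.empty(config.n_iterations)
    for it in range(config.n_iterations):
        draws[it] = _corrected_split_half(cells, n, rng)
    valid = draws[np.isfinite(draws)]
    return valid, int(config.n_iterations - valid.size)


def reliability_overall(
    table: TrialTable, condition: str, config: ResampleConfig
) -> ReliabilityResult:
    """Overall split-half reliability from each participant's full trial set."""
    ids, cells = _eligible_cells(table, condition, 2)
    if len(cells) < MIN_PARTICIPANTS:
        raise InsufficientSampleError(
            f"condition {condition!r}: {len(cells)} participants with >= 2 "
            f"trials (need >= {MIN_PARTICIPANTS})"
        )
    rng = substream(config.seed, "reliability", condition, "overall")
    valid, n_undef = _run_iterations(cells, None, config, rng)
    if valid.size == 0:
        return ReliabilityResult(
            condition, "overall", None, n_undef, False, "all iterations undefined"
        )
    if n_undef:
        log.warning(
            "reliability overall %s: %d/%d iterations undefined (zero variance)",
            condition, n_undef, config.n_iterations,
        )
    summary = summarize_draws(valid, config, None, len(cells))
    return ReliabilityResult(condition, "overall", summary, n_undef)


def reliability_curve(
    table: TrialTable, condition: str, config: ResampleConfig
) -> list[ReliabilityResult]:
    """Reliability at each grid subsample size n, ordered by n.

    A grid point with fewer than 3 eligible participants yields a result
    flagged unavailable instead of aborting the curve.
    """
    if not config.grid:
        raise ValueError("config.grid must be non-empty for a reliability curve")
    results = []
    for n in config.grid:
        ids, cells = _eligible_cells(table, condition, n)
        if len(cells) < MIN_PARTICIPANTS:
            log.warning(
                "reliability %s n=%d: only %d eligible participants; point unavailable",
                condition, n, len(cells),
            )
            results.append(
                ReliabilityResult(
                    condition, "subsample", None, 0, False,
                    f"{len(cells)} eligible participants at n={n}",
                )
            )
            continue
        rng = substream(config.seed, "reliability", condition, n)
        valid, n_undef = _run_iterations(cells, n, config, rng)
        if valid.size == 0:
            results.append(
                ReliabilityResult(
                    condition, "subsample", None, n_undef, False,
                    "all iterations undefined",
                )
            )
            continue
        summary = summarize_draws(valid, config, n, len(cells))
        results.append(ReliabilityResult(condition, "subsample", summary, n_undef))
    return results
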