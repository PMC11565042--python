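"""Within-subject Cohen's d, overall and as a function of trial count.

Per-participant scores are trial means.  Two contrast kinds:

* one-sample — a condition's per-participant means against a baseline
  constant mu0 (default 0; scores are assumed baseline-corrected), with
  d = (mean - mu0) / sd and the one-sample t = d * sqrt(k);
* paired — two conditions' participant-aligned means, with the pooled
  standardizer s = sqrt((s1^2 + s2^2) / 2) (average-variance pooling) and
  the paired t-statistic mean(diff) / (sd(diff)/sqrt(k)) reported alongside.
  The difference-score standardizer d_z = mean(diff)/sd(diff) is available
  as a clearly non-default option; the two are not interchangeable.

Positive d means condition (or condition_1) exceeds the baseline (or
condition_2).  Sample (k-1) standard deviations throughout.

Subsample-scope curves mirror the reliability procedure: per iteration,
subsample n trials per participant per involved condition without
replacement, average, compute d; B iterations give the mean and percentile
CI.  The overall-scope point estimate uses all trials and is deterministic;
its CI comes from a participant-level bootstrap of the all-trial scores,
an explicit interpretation documented in the methods note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientSampleError, UndefinedEffectError
from .io import TrialTable
from .resample import (
    ResampleConfig,
    ResampleSummary,
    subsample_trials,
    substream,
    summarize_draws,
)

__all__ = [
    "OneSampleContrast",
    "PairedContrast",
    "EffectSizeResult",
    "cohens_d_one_sample",
    "cohens_d_paired",
    "effect_size_overall",
    "effect_size_curve",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OneSampleContrast:
    """A condition compared against a fixed baseline constant (default 0 uV)."""

    condition: str
    mu0: float = 0.0

    @property
    def label(self) -> str:
        return f"{self.condition}_vs_baseline({format(self.mu0, 'g')})"

    @property
    def conditions(self) -> tuple[str, ...]:
        return (self.condition,)


@dataclass(frozen=True)
class PairedContrast:
    """Two conditions compared within participants (condition_1 - condition_2)."""

    condition_1: str
    condition_2: str
    standardizer: str = "pooled"  # "pooled" | "dz"

    def __post_init__(self) -> None:
        if self.standardizer not in ("pooled", "dz"):
            raise ValueError("standardizer must be 'pooled' or 'dz'")

    @property
    def label(self) -> str:
        return f"{self.condition_1}_vs_{self.condition_2}"

    @property
    def conditions(self) -> tuple[str, ...]:
        return (self.condition_1, self.condition_2)


Contrast = OneSampleContrast | PairedContrast


@dataclass(frozen=True)
class EffectSizeResult:
    """Per-contrast effect-size summary for one scope.

    For overall scope ``point_estimate`` is the deterministic all-trials d
    and ``summary`` holds the participant-bootstrap distribution; for
    subsample scope the summary is the iteration distribution itself.
    """

    contrast: Contrast
    scope: str  # "overall" | "subsample"
    summary: ResampleSummary | None
    point_estimate: float | None = None
    t_statistic: float | None = None
    available: bool = True
    unavailable_reason: str | None = None

    @property
    def estimate(self) -> float | None:
        if self.point_estimate is not None:
            return self.point_estimate
        return None if self.summary is None else self.summary.mean_estimate

    def to_rows(self) -> list[dict]:
        if not self.available or self.summary is None:
            return []
        s = self.summary
        cond = (
            self.contrast.condition
            if isinstance(self.contrast, OneSampleContrast)
            else self.contrast.condition_1
        )
        return [
            {
                "metric": "effect_size",
                "condition": cond,
                "contrast": self.contrast.label,
                "scope": self.scope,
                "n_trials": s.n_trials,
                "n_iterations": s.n_iterations,
                "n_participants": s.n_participants_used,
                "estimate": self.estimate,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
            }
        ]


def cohens_d_one_sample(
    scores: np.ndarray, mu0: float = 0.0
) -> tuple[float, float]:
    """Cohen's d of per-participant scores against a baseline constant.

    d = (mean - mu0) / sd with the sample (k-1) standard deviation;
    t = d * sqrt(k).
    """
    scores = np.asarray(scores, dtype=float)
    k = scores.size
    if k < 2:
        raise ValueError("need at least 2 scores")
    sd = scores.std(ddof=1)
    if sd == 0.0:
        raise UndefinedEffectError("zero standard deviation across participants")
    d = float((scores.mean() - mu0) / sd)
    return d, d * np.sqrt(k)


def cohens_d_paired(
    scores_1: np.ndarray, scores_2: np.ndarray, standardizer: str = "pooled"
) -> tuple[float, float]:
    """Paired Cohen's d of two participant-aligned score vectors.

    Default standardizer is average-variance pooling
    s = sqrt((s1^2 + s2^2)/2); ``standardizer="dz"`` uses sd of the
    differences instead.  The paired t-statistic is reported alongside
    either way.
    """
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("score vectors must be participant-aligned (equal length)")
    k = s1.size
    if k < 2:
        raise ValueError("need at least 2 participants")
    diff = s1 - s2
    sd_diff = diff.std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = float(diff.mean() / (sd_diff / np.sqrt(k))) if sd_diff > 0 else (
            np.inf * np.sign(diff.mean()) if diff.mean() != 0 else 0.0
        )
    if standardizer == "dz":
        if sd_diff == 0.0:
            raise UndefinedEffectError("zero standard deviation of differences")
        return float(diff.mean() / sd_diff), t
    pooled = np.sqrt((s1.var(ddof=1) + s2.var(ddof=1)) / 2.0)
    if pooled == 0.0:
        raise UndefinedEffectError("zero pooled standard deviation")
    return float(diff.mean() / pooled), t


def _all_trial_scores(
    table: TrialTable, contrast: Contrast, min_trials: int = 1
) -> tuple[list[str], list[np.ndarray]]:
    """Per-condition all-trial mean scores for participants eligible in every
    involved condition."""
    cells_by_cond = [table.cells(c) for c in contrast.conditions]
    ids = sorted(
        set.intersection(
            *(
                {p for p, v in cells.items() if v.size >= min_trials}
                for cells in cells_by_cond
            )
        )
    )
    scores = [
        np.array([cells[p].mean() for p in ids]) for cells in cells_by_cond
    ]
    return ids, scores


def _compute_d(contrast: Contrast, scores: list[np.ndarray]) -> tuple[float, float]:
    if isinstance(contrast, OneSampleContrast):
        return cohens_d_one_sample(scores[0], contrast.mu0)
    return cohens_d_paired(scores[0], scores[1], contrast.standardizer)


def effect_size_overall(
    table: TrialTable, contrast: Contrast, config: ResampleConfig
) -> EffectSizeResult:
    """Deterministic all-trials d with a participant-bootstrap percentile CI."""
    ids, scores = _all_trial_scores(table, contrast)
    k = len(ids)
    if k < 2:
        raise InsufficientSampleError(
            f"contrast {contrast.label}: {k} eligible participants (need >= 2)"
        )
    d_point, t_stat = _compute_d(contrast, scores)
    rng = substream(config.seed, "effect_size", contrast.label, "overall")
    draws = np.empty(config.n_iterations)
    for it in range(config.n_iterations):
        idx = rng.integers(0, k, size=k)
        try:
            draws[it], _ = _compute_d(contrast, [s[idx] for s in scores])
        except UndefinedEffectError:
            draws[it] = np.nan
    valid = draws[np.isfinite(draws)]
    if valid.size == 0:
        return EffectSizeResult(
            contrast, "overall", None, d_point, t_stat, False,
            "all bootstrap iterations undefined",
        )
    summary = summarize_draws(valid, config, None, k)
    return EffectSizeResult(contrast, "overall", summary, d_point, t_stat)


def effect_size_curve(
    table: TrialTable, contrast: Contrast, config: ResampleConfig
) -> list[EffectSizeResult]:
    """Mean d and percentile CI per grid subsample size n, ordered by n.

    Eligibility at n requires >= n trials in every involved condition;
    eligibility is fixed across iterations.  Unavailable grid points are
    flagged, not fatal.
    """
    if not config.grid:
        raise ValueError("config.grid must be non-empty for an effect-size curve")
    results = []
    for n in config.grid:
        ids, cell_lists = _eligible_cell_lists(table, contrast, n)
        k = len(ids)
        if k < 2:
            log.warning(
                "effect size %s n=%d: only %d eligible participants; point "
                "unavailable", contrast.label, n, k,
            )
            results.append(
                EffectSizeResult(
                    contrast, "subsample", None, None, None, False,
                    f"{k} eligible participants at n={n}",
                )
            )
            continue
        rng = substream(config.seed, "effect_size", contrast.label, n)
        draws = np.empty(config.n_iterations)
        for it in range(config.n_iterations):
            scores = [
                np.array([subsample_trials(v, n, rng).mean() for v in cells])
                for cells in cell_lists
            ]
            try:
                draws[it], _ = _compute_d(contrast, scores)
            except UndefinedEffectError:
                draws[it] = np.nan
        valid = draws[np.isfinite(draws)]
        if valid.size == 0:
            results.append(
                EffectSizeResult(
                    contrast, "subsample", None, None, None, False,
                    "all iterations undefined",
                )
            )
            continue
        summary = summarize_draws(valid, config, n, k)
        results.append(EffectSizeResult(contrast, "subsample", summary))
    return results


def _eligible_cell_lists(
    table: TrialTable, contrast: Contrast, n: int
) -> tuple[list[str], list[list[np.ndarray]]]:
    cells_by_cond = [table.cells(c) for c in contrast.conditions]
    ids = sorted(
        set.intersection(
            *({p for p, v in cells.items() if v.size >= n} for cells in cells_by_cond)
        )
    )
    return ids, [[cells[p] for p in ids] for cells in cells_by_cond]
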