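"""Standardized measurement error (SME) for trial-mean amplitude scores.

The SME of a participant's score is the standard error of their trial mean:

* aSME (analytic): SD-hat / sqrt(N), where SD-hat is the estimated (k-1
  denominator) standard deviation across that participant's N trials.  Valid
  for time-window mean amplitudes, where the score from the averaged
  waveform equals the average of single-trial scores.
* bSME (bootstrapped): draw B resamples of size N with replacement from the
  participant's trials, record each resample's mean, and take the SD of
  those B means.  Provided for cross-validation; its large-B limit is
  aSME * sqrt((N-1)/N) because the bootstrap targets the population-style
  SD while aSME uses the k-1 estimate — a documented difference, not a bug.

Only exchangeable per-trial mean-amplitude-type scores are accepted; there
is no waveform, peak-amplitude or latency input path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import TrialTable
from .resample import ResampleConfig, substream

__all__ = ["SMERecord", "SMEGroupSummary", "asme", "bsme", "sme_table", "summarize_sme"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SMERecord:
    """Analytic and bootstrapped SME for one participant x condition cell."""

    participant_id: str
    condition: str
    n_trials: int
    sd_across_trials: float
    asme: float
    bsme: float | None = None
    bsme_iterations: int | None = None

    def to_rows(self) -> list[dict]:
        return [
            {
                "metric": "sme",
                "condition": self.condition,
                "contrast": self.participant_id,
                "scope": "overall",
                "n_trials": self.n_trials,
                "n_iterations": self.bsme_iterations,
                "n_participants": 1,
                "estimate": self.asme,
                "ci_low": None,
                "ci_high": None,
            }
        ]


@dataclass(frozen=True)
class SMEGroupSummary:
    """Group mean SME with a t-interval on between-participant variability."""

    group: tuple[tuple[str, str], ...]  # ((key, value), ...)
    n_participants: int
    mean_asme: float
    mean_bsme: float | None
    ci_low: float
    ci_high: float


def asme(values: np.ndarray) -> float:
    """Analytic SME: sample SD across trials divided by sqrt(N).

    Non-negative, translation-invariant, scale-equivariant; zero iff all
    trials are identical.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("aSME needs at least 2 trials")
    return float(values.std(ddof=1) / np.sqrt(n))


def bsme(values: np.ndarray, n_iterations: int, rng: np.random.Generator) -> float:
    """Bootstrapped SME: SD (k-1 across draws) of B bootstrap-resample means."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("bSME needs at least 2 trials")
    if n_iterations < 2:
        raise ValueError("bSME needs at least 2 bootstrap iterations")
    idx = rng.integers(0, n, size=(n_iterations, n))
    means = values[idx].mean(axis=1)
    return float(means.std(ddof=1))


def sme_table(
    table: TrialTable,
    config: ResampleConfig | None = None,
    compute_bsme: bool = True,
) -> list[SMERecord]:
    """One SMERecord per participant x condition cell with >= 2 trials.

    Cells with a single trial are skipped with a logged warning.  Bootstrap
    streams derive from the config seed per cell, so records are
    deterministic under a fixed seed and independent of table ordering.
    """
    config = config or ResampleConfig()
    records = []
    counts = table.cell_counts()
    for row in counts.itertuples(index=False):
        pid, cond = str(row.participant), str(row.condition)
        values = table.trials(pid, cond)
        if values.size < 2:
            log.warning(
                "skipping %s/%s: %d trial(s), need >= 2 for SME", pid, cond, values.size
            )
            continue
        sd = float(values.std(ddof=1))
        rec_bsme = None
        if compute_bsme:
            rng = substream(config.seed, "sme", pid, cond)
            rec_bsme = bsme(values, config.n_iterations, rng)
        records.append(
            SMERecord(
                participant_id=pid,
                condition=cond,
                n_trials=int(values.size),
                sd_across_trials=sd,
                asme=float(sd / np.sqrt(values.size)),
                bsme=rec_bsme,
                bsme_iterations=config.n_iterations if compute_bsme else None,
            )
        )
    return records


def summarize_sme(
    records: list[SMERecord],
    by: tuple[str, ...] = ("condition",),
    ci_level: float = 0.95,
) -> list[SMEGroupSummary]:
    """Group means of aSME/bSME with a t-interval on between-participant SD.

    ``by`` names SMERecord fields to group on (typically ``("condition",)``).
    Groups with fewer than 2 records are skipped with a warning (no CI is
    defined).  The interval describes variability between individuals:
    mean +/- t_{1-(1-level)/2, m-1} * SD / sqrt(m).
    """
    groups: dict[tuple, list[SMERecord]] = {}
    for rec in records:
        key = tuple((k, str(getattr(rec, k))) for k in by)
        groups.setdefault(key, []).append(rec)
    out = []
    for key in sorted(groups):
        members = groups[key]
        m = len(members)
        if m < 2:
            log.warning("group %s has %d record(s); skipped (CI undefined)", key, m)
            continue
        a = np.array([r.asme for r in members])
        bs = [r.bsme for r in members]
        mean_b = float(np.mean(bs)) if all(b is not None for b in bs) else None
        tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df=m - 1)
        half = float(tcrit * a.std(ddof=1) / np.sqrt(m))
        out.append(
            SMEGroupSummary(
                group=key,
                n_participants=m,
                mean_asme=float(a.mean()),
                mean_bsme=mean_b,
                ci_low=float(a.mean() - half),
                ci_high=float(a.mean() + half),
            )
        )
    return out
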