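"""Variance-components generator of trial-level tables with known truth.

Generating model, per participant i, condition c, trial t:

    value_ict = mu_c + b_i + e_ict,   b_i ~ N(0, sigma_b^2),
                                      e_ict ~ N(0, sigma_w^2)

The subject effect b_i is shared across conditions, so between-condition
null contrasts have positively correlated participant scores — exercising
the paired path realistically.  Condition effects enter as mean shifts only
(no subject x condition interaction), keeping the paired-d oracle simple;
an optional interaction SD is available as an extension knob without an
oracle.

Single-trial reliability is rho = sigma_b^2 / (sigma_b^2 + sigma_w^2), and
three closed-form oracles follow:

* reliability of an n-trial mean (Spearman-Brown prophecy):
  R(n) = n*rho / (1 + (n-1)*rho)
* one-sample effect size at n trials: d(n) = mu_c / sqrt(sigma_b^2 + sigma_w^2/n)
* expected aSME at n trials: approximately sigma_w / sqrt(n)

Gaussian noise is the default for closed-form tractability; a heavy-tailed
scaled-t option (variance renormalized to sigma_w^2) exists for robustness
checks and is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TrialTable

__all__ = [
    "SyntheticSpec",
    "generate_trial_table",
    "expected_reliability",
    "expected_effect_size",
    "expected_asme",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the variance-components generating model.

    Parameters
    ----------
    n_subjects
        Number of participants.
    n_trials
        Trials per participant x condition: an integer for balanced tables,
        or an inclusive (min, max) range for ragged counts drawn uniformly
        per cell.
    mu
        Grand mean per condition (score units, e.g. microvolts).  A single
        float applies to every condition; a dict maps condition -> mean.
    sigma_b
        Between-subject SD of the true scores (>= 0).
    sigma_w
        Within-subject trial-noise SD (>= 0).
    conditions
        Condition tokens.
    seed
        Generator seed; the output table is deterministic per seed.
    noise
        "normal" (default) or "t" for scaled-t trial noise (df ``t_df``,
        rescaled so the noise SD stays sigma_w).
    sigma_interaction
        Optional subject x condition interaction SD; no closed-form oracle
        covers it, so it defaults to 0.
    """

    n_subjects: int
    n_trials: int | tuple[int, int]
    mu: float | dict[str, float] = 0.0
    sigma_b: float = 1.0
    sigma_w: float = 1.0
    conditions: tuple[str, ...] = ("A",)
    seed: int = 0
    noise: str = "normal"
    t_df: float = 5.0
    sigma_interaction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if isinstance(self.n_trials, tuple):
            lo, hi = self.n_trials
            if lo < 1 or hi < lo:
                raise ValueError("n_trials range must satisfy 1 <= min <= max")
        elif self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.sigma_b < 0 or self.sigma_w < 0 or self.sigma_interaction < 0:
            raise ValueError("SD parameters must be non-negative")
        if self.noise not in ("normal", "t"):
            raise ValueError("noise must be 'normal' or 't'")
        if self.noise == "t" and self.t_df <= 2:
            raise ValueError("t noise needs t_df > 2 for a finite variance")
        if not self.conditions:
            raise ValueError("need at least one condition")

    def mean_of(self, condition: str) -> float:
        if isinstance(self.mu, dict):
            return float(self.mu[condition])
        return float(self.mu)

    @property
    def rho(self) -> float:
        """Single-trial reliability sigma_b^2 / (sigma_b^2 + sigma_w^2)."""
        denom = self.sigma_b**2 + self.sigma_w**2
        if denom == 0:
            raise ValueError("rho undefined when sigma_b = sigma_w = 0")
        return self.sigma_b**2 / denom


def generate_trial_table(spec: SyntheticSpec) -> TrialTable:
    """Draw a trial-level table from the variance-components model."""
    rng = np.random.default_rng(spec.seed)
    subjects = [f"S{i + 1:04d}" for i in range(spec.n_subjects)]
    b = rng.normal(0.0, spec.sigma_b, size=spec.n_subjects) if spec.sigma_b > 0 else (
        np.zeros(spec.n_subjects)
    )
    parts: list[pd.DataFrame] = []
    for cond in spec.conditions:
        mu_c = spec.mean_of(cond)
        inter = (
            rng.normal(0.0, spec.sigma_interaction, size=spec.n_subjects)
            if spec.sigma_interaction > 0
            else np.zeros(spec.n_subjects)
        )
        for i, sid in enumerate(subjects):
            if isinstance(spec.n_trials, tuple):
                k = int(rng.integers(spec.n_trials[0], spec.n_trials[1] + 1))
            else:
                k = int(spec.n_trials)
            noise = _trial_noise(rng, spec, k)
            values = mu_c + b[i] + inter[i] + noise
            parts.append(
                pd.DataFrame(
                    {
                        "participant": sid,
                        "condition": cond,
                        "trial": np.arange(1, k + 1),
                        "value": values,
                    }
                )
            )
    return TrialTable(pd.concat(parts, ignore_index=True))


def _trial_noise(rng: np.random.Generator, spec: SyntheticSpec, k: int) -> np.ndarray:
    if spec.sigma_w == 0:
        return np.zeros(k)
    if spec.noise == "t":
        raw = rng.standard_t(spec.t_df, size=k)
        return spec.sigma_w * raw / np.sqrt(spec.t_df / (spec.t_df - 2.0))
    return rng.normal(0.0, spec.sigma_w, size=k)


def expected_reliability(spec: SyntheticSpec, n: int) -> float:
    """Prophecy oracle R(n) = n*rho / (1 + (n-1)*rho) for an n-trial mean."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rho = spec.rho
    return n * rho / (1.0 + (n - 1) * rho)


def expected_effect_size(spec: SyntheticSpec, condition: str, n: int) -> float:
    """One-sample oracle d(n) = mu_c / sqrt(sigma_b^2 + sigma_w^2 / n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    denom = np.sqrt(spec.sigma_b**2 + spec.sigma_w**2 / n)
    if denom == 0:
        raise ValueError("effect size undefined when sigma_b = sigma_w = 0")
    return float(spec.mean_of(condition) / denom)


def expected_asme(spec: SyntheticSpec, n: int) -> float:
    """Expected analytic SME of an n-trial cell: approximately sigma_w/sqrt(n)."""
    if n < 2:
        raise ValueError("aSME needs n >= 2")
    return float(spec.sigma_w / np.sqrt(n))
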