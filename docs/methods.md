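# Methods

## Scope and input contract

`trialqc` consumes trial-level single scores — one finite real number per
(participant, condition, trial) — and nothing upstream of them.  Scores are
assumed to be already baseline-corrected time-window mean amplitudes (or
per-epoch power values); the package deliberately has no waveform, peak
amplitude or peak-latency path, because the analytic SME below is only
valid for scores that commute with averaging (the mean of single-trial
window means equals the window mean of the average waveform).  Trial counts
may be ragged across participants and conditions; missing trials are simply
absent records, and a blank cell in the wide CSV layout means "absent",
never zero, since zero microvolts is a legal amplitude.

## Split-half reliability

Per iteration and participant: draw n trials uniformly without replacement
(overall scope uses the participant's full trial set), partition them
uniformly into bins of floor(k/2) and ceil(k/2), average each bin, then
Pearson-correlate the two bin-mean vectors across participants and apply
the Spearman-Brown correction r_full = 2r_half/(1+r_half).  The iteration
distribution over B repeats is summarized by its arithmetic mean and
percentile interval.

Choices made where the procedure is genuinely open:

* **Correlation type** — Pearson, the convention under which the
  Spearman-Brown correction is derived.
* **Minimum participants** — 3; with 2 the correlation is ±1 by
  construction.
* **Negative r_half** — passed through the correction unclamped and
  reported as computed; truncating at zero would bias the iteration mean
  upward.  r_half = −1 (and any iteration with a zero-variance bin-mean
  vector) has no defined estimate; such iterations are dropped from the
  summary and counted in `n_undefined`.
* **Eligibility** — a participant with fewer than n trials is excluded
  from grid point n, for all iterations; `n_participants_used` is therefore
  constant per n and reported.  Exclusion was chosen over padding or
  sampling with replacement because both alternatives change the estimand.
* **Odd n** — near-equal bins with the correction applied unchanged.  The
  halves then estimate slightly unequal test lengths, giving a small
  downward bias (≈0.007 at n = 5, ρ = 0.2, from the unequal-length
  correlation σ_b²/√((σ_b²+σ_w²/⌊n/2⌋)(σ_b²+σ_w²/⌈n/2⌉))); this is
  documented rather than "corrected".
* **Iteration averaging** — arithmetic mean of the corrected coefficients.
  A Fisher-z mean was considered and rejected as the default because the
  plain mean is what the iteration-distribution CI describes.

## Effect sizes

Per-participant scores are trial means.  One-sample contrasts use
d = (x̄ − μ0)/s with the sample (k−1) SD and t = d√k; μ0 defaults to 0
because inputs are baseline-corrected.  Paired contrasts standardize the
mean difference by average-variance pooling s = √((s₁²+s₂²)/2) — a literal
pooled SD of the two score vectors — with the paired t reported alongside.
The difference-score standardizer d_z = mean(diff)/sd(diff) is available
but clearly non-default; the two answer different questions and are not
interchangeable.  Positive d means the first condition exceeds the baseline
(or the second condition); swapping the conditions negates d exactly.

Subsample-scope curves reuse the reliability loop (eligibility at n
requires ≥ n trials in *every* involved condition).  The overall-scope d is
deterministic given all trials, so its CI cannot come from trial
resampling; we draw it from a participant-level bootstrap (resampling
participants with replacement B times and recomputing d).  This is an
interpretation — the iteration-distribution mechanism for overall CIs is
otherwise unspecified — and it measures across-participant sampling
variability, which is what an error bar on a single deterministic d can
meaningfully show.

Note one consequence of percentile CIs from trial resampling: at n equal to
a participant's full trial count the subsample is the whole set, the
iteration distribution collapses to the sample d, and the CI has zero
width.  These CIs describe resampling variability, not sampling error
across cohorts.

## Standardized measurement error

aSME = SD̂/√N per participant × condition cell, with SD̂ using the N−1
denominator ("estimated" SD).  bSME draws B resamples of size N with
replacement, records each resample's mean, and returns the SD (again k−1,
across the B means) of that sampling distribution.  The large-B limit of
bSME is aSME·√((N−1)/N), because the bootstrap targets the population-style
SD of the resampling distribution while aSME uses the k−1 estimate; the
√((N−1)/N) factor is a property of the pair of definitions, tested as such
and not adjusted away.  Cells with one trial yield no record and a logged
warning.  Group summaries report mean aSME/bSME with a t-interval on the
between-participant SD, mean ± t_{1−α/2, m−1}·SD/√m — the caption-level
"variability between individuals" made concrete with the standard
small-sample interval.

## Resampling machinery

Percentile intervals use linear interpolation between order statistics
(quantile q at fractional position 1 + q(B−1) in the sorted draws — the
numpy `linear` method).  All randomness derives from one master seed;
per-(metric, condition, n) substreams are spawned via SHA-256-hashed keys
feeding a `SeedSequence`, so adding a grid point or another condition never
perturbs existing draws.  Determinism is promised within this
implementation (identical inputs + seed → byte-identical result CSVs);
bit-equality across numpy versions or other implementations is not,
statistical equality is.

## Synthetic generator and oracles

The generator draws value_ict = μ_c + b_i + e_ict with b_i ~ N(0, σ_b²)
shared across conditions and e_ict ~ N(0, σ_w²).  It emulates exactly the
statistical structure the metrics assume: stable subject-level true scores,
exchangeable within-cell trial noise, condition mean shifts, optional
ragged trial counts (drawn uniformly per participant × condition when a
(min, max) range is given).  It does **not** emulate serial dependence
between trials (habituation, drift), non-stationary noise, artifact-driven
outliers, subject × condition interactions (available as an optional SD
knob, without an oracle), or any waveform structure — so passing recovery
tests shows the estimators are correct under the model, not that real
infant EEG satisfies the model.  A scaled-t noise option (variance
renormalized to σ_w²) exists for heavy-tail robustness checks and is off by
default; Gaussian components are the default because they make the three
oracles exact:

* R(n) = nρ/(1+(n−1)ρ) with ρ = σ_b²/(σ_b²+σ_w²),
* d(n) = μ_c/√(σ_b²+σ_w²/n) for one-sample contrasts,
* E[aSME at n trials] ≈ σ_w/√n.

## Verification design and problem sizes

Formula-level functions are checked against hand computations to six
significant digits.  The split-half Monte Carlo is checked against
exhaustive enumeration of all 2³ bin assignments for a 3-participant,
2-trial table at B = 20 000 (tolerance 0.01).  Recovery checks run 200
participants at B = 1000 — reliability at n ∈ {5, 10, 20, 40} against the
prophecy oracle (±0.03), effect sizes at n ∈ {4, 16, 64} against d(n)
(±0.06) — averaged over 12 independently simulated cohorts, because a
single finite cohort's realized reliability differs from the population
value by subject-sampling error (SE ≈ 0.03 at n = 5 with 200 participants)
while the oracle predicts the estimator's expectation; the replicate
average isolates estimator bias from cohort luck.  The acceptance script
uses 6 replicate cohorts at the same conditions.  bSME/aSME consistency is
checked at B = 5000 on 20-trial fixtures and against the exhaustive
two-trial bootstrap SD (√0.5) at B = 50 000.  The overall split-half mean
on a balanced 500 × 10 table is cross-checked against Cronbach's alpha
computed independently (alpha equals the average corrected split-half
coefficient over all splits on tau-equivalent items, so agreement within
0.05 is expected, not exact equality).

## Plotting and CLI

Reliability curves carry the conventional threshold lines (.60 red dotted,
.80 black solid, .90 black dotted); effect-size curves carry none by
default.  The overall estimate is drawn as a separate annotated point
beyond the grid.  Because rendered PNG bytes can differ across matplotlib
builds, the determinism contract for plots is carried by a JSON sidecar
(`<image>.json`) that records every plotted number and threshold and is
byte-stable for identical inputs.  Each CLI run writes a manifest
(subcommand, resolved config, seed, SHA-256 of the input) from which every
number in the result CSVs is recomputable; result CSVs render numbers with
8 significant digits and are byte-identical across re-runs of an identical
manifest.

## Known limitations

* Overall-scope reliability splits each participant's full ragged trial
  set without equalizing counts across participants; participants with more
  trials contribute more precise half-means.
* The percentile CIs describe resampling variability conditional on the
  sample, not population sampling error (except the overall effect-size CI,
  which bootstraps participants).
* No generalizability-theory coefficients, no signal-to-noise ratio, no
  peak-amplitude/latency SME, and no SME-based exclusion thresholds — no
  defensible universal threshold for acceptable SME exists.
* Cronbach's alpha is retained only as a cross-check, not as an estimator:
  it assumes a fixed item (trial) order and its value depends directly on
  the trial count, both problematic for ERP paradigms.
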