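# Methods

## Spectral estimation

The estimator is a segment-averaged windowed periodogram. Each 30-s
epoch is cut into six contiguous 5-s segments (625 samples at 125 Hz);
a segment is mean-removed, tapered with a periodic Hanning window and
discrete-Fourier transformed. Powers are normalised by `N · Σw²` and
folded one-sided, the Welch convention under which the total one-sided
power of a stationary signal is an unbiased estimate of its variance —
the white-noise Parseval test in the suite verifies this within 3
standard errors over 1000 segments, and a brute-force direct-DFT oracle
confirms bit-level agreement (1e-9 relative) of the fast path.

Choices the estimator definition leaves open, and how they are fixed
here:

* **Mean removal per segment.** Applied before windowing. The analysis
  range starts at 0.8 Hz, and a DC offset would otherwise leak into
  the first analysed bins through the window's main lobe.
* **Window normalisation.** Division by the window's summed square
  (equivalently mean-square), making broadband power unbiased. An
  amplitude-flatness normalisation (`Σw`) would instead make isolated
  sinusoid peaks exact but bias noise power; broadband EEG argues for
  the former.
* **Band edges.** Bands are half-open `[lo, hi)` with shared edges
  (4, 8, 12, 15 Hz) assigned to the upper band. Prose band notation
  ("1–4, 4–8 Hz") double-books the edges; half-open intervals make the
  five band powers sum exactly to the 1–20 Hz integral, which the
  suite asserts.
* **Channel averaging** happens at the band-power level,
  (C3/A2 + C4/A1)/2, not on the raw signals — averaging raw signals
  would cancel incoherent activity and underestimate power.
* **Aggregation order.** Per state the participant value is
  log₁₀(mean epoch power), not mean(log power). The log transform
  exists to normalise the *participant-level* distribution; averaging
  in the power domain keeps the epoch mean interpretable as total
  energy over the state.
* **Trailing partial epochs** (recording shorter than hypnogram ×
  30 s) are discarded; epoch *k* covers samples `[k·30·fs, (k+1)·30·fs)`.
* No artifact rejection is performed beyond the < 0.8 Hz exclusion.

## Sleep-state stratification

Hypnogram stages N1/N2/N3 form the NREM set, R the REM set, and their
union the TOTAL sleep set; wake epochs never contribute. Stage-4 epochs
scored under the older R&K rules are merged into N3 on read, matching
modern reporting. PSG architecture metrics use conventional
definitions the source tables leave implicit: sleep onset = first
non-wake epoch, WASO = wake epochs after onset, REM latency = onset to
first REM epoch, stage percentages relative to total sleep time.

## Group classification and inclusion

The four-group rule (NI / INH / HNI / HI, anything else EXCLUDED) is a
partition: an exhaustive check over all 5⁴ = 625 response vectors
verifies mutual exclusivity against an independent restatement of the
rules. EXCLUDED is a label, not an error — unclassifiable respondents
are silently dropped by the inclusion cascade, which removes (in
order) participants without a group, without complete spectral
summaries, and missing alcohol, medication, or smoking data, reporting
per-reason counts.

## Statistics

* **Chi-square** is Pearson's statistic without continuity correction;
  this exactly reproduces published 4×2 group-by-trait statistics from
  their printed counts (five such tables are frozen in the acceptance
  suite at 2-decimal agreement).
* **One-way ANOVA** is computed from per-group summary statistics
  (SSB = Σ n_g(m_g − m̄)², SSW = Σ (n_g − 1)s_g²); the raw-data entry
  point reduces to it and is cross-checked against
  `scipy.stats.f_oneway`. Degenerate inputs (zero within-group
  variance) report F = 0 or ∞ with a flag instead of 0/0.
* **ANCOVA** fits `outcome ~ group + covariates` by OLS; the group
  effect is the extra-sum-of-squares F from dropping the group dummies
  — for a single factor plus covariates this equals the Type III test,
  and with no covariates it collapses to one-way ANOVA (asserted to
  1e-9). Adjusted means are predictions at covariate means. Post-hoc
  comparisons are pairwise contrasts of adjusted means on the model's
  coefficient covariance, two-sided t, each p multiplied by the number
  of pairs (6 for four groups) and capped at 1. Covariates enter
  untransformed (continuous age/AHI/alcohol, binary flags); rank
  deficiency raises an error naming the collinear columns, and
  constant covariates are dropped before subset re-analyses where they
  carry no information.
* **Family corrections** multiply raw p by 5 (total-sleep band family)
  or 10 (NREM + REM), capped at 1; report rendering prints values
  above 0.999 as "> 0.999".
* **Propensity matching** fits an unpenalised logistic regression of
  treated-vs-control membership on a binned design — age groups <50 /
  50–59 / 60–69 / ≥70, sex, AHI > 15, alcohol per day, smoking, and
  the three medication flags (binning is used only here, never in the
  ANCOVA). Treated participants are processed in descending propensity
  order; each takes its `ratio` nearest unused controls by absolute
  logit distance, exact ties broken by a seeded random ordering. Both
  the ordering and the tie-break are fixed conventions chosen for
  reproducibility; matching is without replacement and errors rather
  than silently degrading when controls run short (a partial mode is
  available behind a flag).

## Synthetic cohort

The generator has two tiers because their jobs differ:

* The **feature tier** produces the participant table at full cohort
  size — default group sizes 1386 / 401 / 133 / 65 and per-group
  band-log-power targets and covariate distributions taken from the
  emulated cohort's published group summaries (e.g. total-sleep sigma
  0.224 in NI vs 0.387 in HI, between-participant SD ≈ 0.19–0.23 per
  band). Band outcomes are Gaussian around the group target;
  questionnaire responses are drawn uniformly among the vectors
  consistent with the group's rule (so classification round-trips by
  construction, which a test asserts); ages are truncated at 40
  (the cohort enrolled adults over 40), AHI and ESS at 0, and
  alcohol/day uses a gamma law since its SD exceeds its mean.
  Covariate→EEG coefficients default to 0 — the emulated study reports
  no such coefficients, only covariate-adjusted group tests — and can
  be switched on (`covariate_effects`) for confounding experiments.
* The **raw tier** synthesises two-channel 125 Hz EEG against a
  first-order Markov hypnogram. Per epoch, each channel is an
  independent sum of band-limited Gaussian processes shaped in the
  rFFT domain, flat within each band, scaled so the expected
  integrated band power equals `10^target`; a closed-form check
  (time-domain variance = target) anchors the tests. Flat-in-band is
  the simplest spectrum with that closed form; real EEG is closer to
  1/f within bands, so absolute within-band shape is *not* emulated.
  The default transition matrix was chosen so the chain's stationary
  law matches typical cohort sleep architecture (≈ 4/57/20/19 % of
  sleep in N1/N2/N3/REM, ~11 % wake); sequences start from the
  stationary distribution to avoid an initialisation transient. An
  optional 0.3 Hz sinusoidal drift, added after the stochastic draw so
  the noise stream is unchanged, exercises the low-frequency
  exclusion.

What passing tests on this cohort do **not** show: robustness to real
EEG nonstationarity, discrete spindles and arousals, artifact epochs,
or the empirical covariate–EEG confounding structure — with
coefficients at 0, covariate adjustment does not attenuate the
simulated group effect the way it does in observational data, so
simulated ANCOVA F values exceed published ones even when group means
and SDs match. Raw-tier recovery of band targets is limited to
≈ 0.03–0.05 log₁₀ μV² by deterministic Hann leakage across band edges
(power flows from stronger into adjacent weaker bands), the same bias
any segment-windowed implementation of this estimator has.

The benzodiazepine covariate stays imbalanced even after matching
(prevalence ≈ 43 % in HI vs ≈ 1.4 % in NI leaves too few exposed
controls); this mirrors the structural imbalance of the emulated
cohort and is visible in the balance table the matched-analysis script
writes.

## Problem sizes and determinism

Analysis drivers run the full 1985-participant feature tier; raw-tier
validation uses four 2-h nights, and test fixtures use reduced cohorts
(hundreds of participants, 1–2 h recordings) — enough for every
estimator to be exercised at its asymptotics while keeping the whole
suite fast. Monte-Carlo calibration uses 200 replicates for power at
the study's group sizes and 1000 for type-I error. Every stochastic
path takes a `numpy.random.default_rng` seed; pipelines with equal
(config, seed) produce byte-identical CSVs.

## File formats

Signals are plain EDF: 16-bit, 1-s records, physical dimension μV,
default physical range ±500 μV with a symmetric digital range
(−32767…32767) so 0 μV is exactly representable; round-trip error is
at most half an LSB (≈ 0.0076 μV). EDF+ annotations and vendor staging
XML are out of scope. Hypnograms are newline- or comma-separated stage
tokens (`W,N1,N2,N3,R`, synonyms `WAKE,S1–S4,REM`, or R&K numeric codes
0–5 with 3 and 4 both mapping to N3). Channel labels match after
case-folding and punctuation stripping, so `EEG C3-A2` and `c3/a2`
both resolve to the C3-A2 derivation.
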