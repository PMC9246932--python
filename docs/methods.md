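# Methods

This package re-implements, as a tested pipeline, the behavioural analysis
of a speeded bisensory detection task: participants press a button as fast
as possible to auditory (A), visual (V) or audiovisual (AV) stimuli
presented in random order with equal probability and interstimulus
intervals (ISI) jittered uniformly on 1–3 s. The core questions are whether
redundant (AV) stimulation speeds responses beyond statistical
facilitation, how that changes with age and diagnosis, and how sequential
(modality-switch) effects and channel dependency shape it.

## Quantile CDFs

All distribution-level analyses work on "vertical" empirical CDFs: for each
subject, RTs of the three conditions are evaluated as cumulative
probabilities P(RT ≤ t_k) at 20 linearly spaced latencies t_k between
pooled cutoffs — the smallest per-condition 2.5th percentile and the
largest per-condition 97.5th percentile. Probabilities, not interpolated
latencies, are compared across conditions, so unequal trial counts are
unproblematic. Ties at an evaluation point count as ≤ t (closed on the
right), which fixes bit-level reproducibility. Areas over the unit quantile
interval are computed as the arithmetic mean of the 20 per-quantile
differences (rectangle rule); this makes the decomposition
`gain = benefit_emp − benefit_pred` an exact algebraic identity rather than
a numerical approximation.

## Race models and benefits

Raab's independent race predicts
`F_A∪V(t) = F_A(t) + F_V(t) − F_A(t)·F_V(t)`. Grice's bound
`max(F_A, F_V)` and Miller's bound `min(F_A + F_V, 1)` bracket it;
`grice ≤ raab ≤ miller` is asserted exactly. The conditioned variant
splits each unisensory CDF by the preceding stimulus modality
m ∈ {A, V, AV}, races the pair within each stratum, and averages the three
races with equal weights 1/3 (matching the printed formula; not
trial-weighted). Because per-stratum fast- and slow-channel CDFs are
anticorrelated under switch costs, the mean of per-stratum races exceeds
the race of pooled CDFs — the conditioned model predicts *more*
facilitation, i.e. a less conservative facilitation estimate. Predicted and
empirical benefits are areas between the race (resp. AV) CDF and Grice's
bound; multisensory gain is the area between the AV CDF and the race CDF,
equal to the sum of its positive and negative parts.

Degenerate preceding-modality strata (fewer than 5 RTs by default) fall
back to the unconditioned CDF for that term, with a warning; if every
stratum is degenerate the conditioned race is refused.

## Competition bias models

Model 1 predicts the AV CDF as the preceding-modality average of a single
biased channel b (auditory: 1A, visual: 1V); Model 2 uses the
previous-trial channel, with b as default after AV trials:
`F_2b = (F_A(A,·) + F_V(V,·) + F_b(AV,·)) / 3`. A mixture probability
p ∈ {0, 0.25, 0.5, 0.75, 1} interpolates linearly between the conditioned
race (p = 0) and the bias model (p = 1); the mixture benefit is affine in p
by construction. Models are scored by the between-subject Pearson
correlation between predicted and empirical benefits within age groups
(6–9, 10–12, 13–17, 18–40 at integer age), with two-tailed permutation
significance.

## Switch effects

The modality switch effect (MSE) is the area between repeat- and
switch-trial CDFs of a condition (positive = switching slows). AV→A and
AV→V transitions are neither switches nor repeats and are excluded; A→AV
and V→AV are pooled for the main AV effect and kept separate for the
dominance analysis, where they are normalised by the pooled effect at the
age-group level (group means, not per subject, to avoid division by
near-zero individual references). A mean-RT variant reports
switch-minus-repeat in milliseconds, optionally restricted by the preceding
ISI. Race tests can be run within the switch and repeat partitions
separately, sharing the subject's pooled evaluation grid so the two gains
are comparable.

## LATER channels and the context race model

Unisensory RTs follow the LATER assumption: rates x = 1000/RT (1/s) are
normal with mean μ and SD σ, fitted by maximum likelihood (sample mean and
MLE SD of the rates). The context-variant race model predicts AV RTs as
1000/max(X_A, X_V), with (X_A, X_V) bivariate normal at the fitted
unisensory means, correlation ρ, and SDs inflated multiplicatively by
1 + η. η is parameterised as a common multiplicative inflation of both
channel SDs; this choice is isolated behind one function so alternatives
are swappable. The max distribution uses its closed-form density (two
conditional-normal terms) and the bivariate-normal CDF; a 10⁶-draw sampling
oracle confirms agreement within 0.005. (ρ, η) are fitted by maximising the
AV log-likelihood with a bounded Powell search from five deterministic
starts (ρ ∈ [−0.99, 0.99], η ∈ [0, 3]); non-convergence is flagged with
best-so-far parameters. With ρ = η = 0 the model reduces exactly to Raab's
race of the two LATER channels.

## Inference layer

- **Permutation tests** (default 10,000 permutations): one-sample/paired
  tests flip signs, two-sample tests shuffle labels; the p-value uses the
  add-one estimator and is never zero. Multivariate tests are corrected
  familywise by the permutation distribution of the maximum statistic
  (tmax) or by Benjamini–Hochberg FDR (used for moving-window analyses,
  q = 0.05). Zero-variance inputs yield p = 1, not an error.
- **BCa bootstrap** intervals (default 10,000 resamples) via
  `scipy.stats.bootstrap`; constant data returns a zero-width interval.
- **Hedges g**: pooled-SD standardised difference with the small-sample
  correction J = 1 − 3/(4·df − 1); CI by BCa bootstrap.
- **Bayes factors**: JZS construction with a Cauchy prior of scale 1
  (via pingouin's numerical integration); reported as BF01 (evidence for
  the null).
- **RIN transform**: rankits Φ⁻¹((rank − ½)/n) with mid-ranks for ties.
- **Similarity matrices**: pairwise RMSE and (RIN-transformed) Pearson
  correlation between subjects' 20-point difference functions, averaged
  within 2.5-year age-bin pairs on 6–21 years; the row-wise argmin/argmax
  trace reads off developmental lag.
- **Matching**: controls matched exactly on sex, then nearest neighbour on
  standardised (age, PIQ), without replacement; equidistant candidates
  break ties by the lower subject id (deterministic).
- **Moving windows**: 7-year windows stepped by 1 year over 6–26;
  per-window group means, BCa CIs, two-tailed permutation tests (FDR
  across windows) and BF01; windows with fewer than 3 per group are
  omitted.
- **Mixed model**: trial-level RTs with contrast-coded group, continuous
  age, and condition (AV reference) as fixed effects; random intercepts
  for subject, ISI and preceding modality with by-subject and
  by-preceding-modality condition slopes, fitted by ML via statsmodels
  variance components. ISI enters the random structure binned into deciles
  (a continuous variable cannot index a grouping factor).
- **Mediation**: age → MSE → gain on z-scored variables; paths from three
  OLS regressions, so a·b + c′ = c exactly; the indirect effect a·b gets a
  BCa-adjusted bootstrap SE and p; full vs partial mediation classified by
  the significance of the direct path c′.

## Synthetic cohort generator

The generator realises the statistical structure the analyses assume, so
every stage is testable end to end without external data:

- Conditions i.i.d. equiprobable; ISIs uniform on 1000–3000 ms; blocks of
  100 trials (default 8 blocks = 800 trials, configurable; the task
  protocol reports ~100-trial blocks, 6–10 per participant).
- Unisensory RT = 1000/X with X ~ N(μ_c, σ_c) truncated positive by
  rejection (negligible mass at the default rates). Channel rates are
  age-linear up to age 24 — e.g. the NT auditory channel runs
  μ_A = 2.10 + 0.062·min(age, 24) 1/s with σ = 0.55 + 0.008·min(age, 24),
  the visual channel 0.25 1/s slower, and the ASD group 0.12 1/s slower —
  values chosen so median RTs span roughly 430 ms (age 6) to 280 ms
  (adults) with realistic spread.
- Idiosyncratic between-subject variation: a shared rate shift
  (SD 0.35 1/s) plus half-size channel-specific shifts, σ jitter
  (SD 0.06), and switch-cost jitter (SD 0.15). These spreads are what make
  between-subject correlation analyses (model selection, benefit
  regressions) informative; they approximate the large inter-individual
  variability of child cohorts.
- Switch costs subtract from the rate mean (LATER-consistent) for any
  channel absent on the previous trial; default 0.25 1/s (≈ 30 ms at
  adult rates), optionally decaying exponentially with the preceding ISI,
  and separately controllable on AV trials.
- AV trials draw (X_A, X_V) with correlation ρ and SDs inflated by 1 + η,
  respond at 1000/max. Defaults follow the developmental pattern: ρ(age) =
  0.45 − 0.03·min(age, 24) (positive in childhood, ≈ −0.27 in adults),
  η = 0.1. Under a competition regime, with probability p the response is
  drawn solely from the biased channel (fixed or previous-modality,
  matching the four bias models).
- Misses are absent rt_ms (default 5%); false alarms are a per-subject
  count consumed only by accuracy scoring (no stimulus-locked FA records);
  occasional double presses (0.5%) exercise the cleaning rules.
- All randomness flows from one seed sequence (one child stream per
  subject): identical config + seed ⇒ byte-identical tables.

What the generator does *not* emulate: non-normal rate distributions
(express responses, lapses with slow recovery), within-session fatigue or
learning drifts, higher-order (n−2) sequence effects, and any particular
public dataset's exact distributions. Passing tests therefore show that
the estimators recover the structure they assume, not that real cohorts
satisfy those assumptions.

## Cleaning and exclusions

Trials are dropped for double presses, the first three trials per block
(training), ISIs outside 1–3 s, missing responses, and RTs outside
100–2000 ms; then per-condition RTs outside that condition's 2.5–97.5
percentile interval (linear interpolation, boundaries retained) are
trimmed. Re-cleaning with the reported limits is the identity; recomputing
limits on cleaned data would trim again, which is why the limits are part
of the cleaning report. The percentile trim is known to shift the race
comparison slightly positive (the AV fast tail is trimmed relative to the
pooled window, ≈ +0.007 AUC under the null generator); this is a property
of the published cleaning procedure and is documented rather than
"corrected". Subjects are excluded for age outside 6–40, PIQ < 80 or
missing, accuracy (F1) more than 3 SD below the cohort mean, false alarms
exceeding 65% of trials, hits in one modality below 50% of the other,
out-of-range ISIs, or fewer than 20 RTs in any condition; the accuracy
threshold is evaluated on the candidate pool before RT-based exclusions.

## Problem sizes and numerical choices

Validation simulations use sizes chosen for a single-CPU run: 100
replicates for (ρ, η) recovery (400 AV trials each) and for
model-selection recovery (40 subjects × 1000 trials per cohort), 500 null
cohorts for the familywise-error audit (2000 permutations each), 1000
replicate datasets for BCa coverage, and 10⁶ draws for the Monte-Carlo
oracles. Pooled percentile limits are computed after the per-condition
trim (limits describe retained data). Permutation p-values use the add-one
rule; optimiser tolerances are xtol 1e-4 / ftol 1e-6.

## Known limitations

- The (ρ, η) likelihood ignores sequential structure; fitting data with
  strong switch costs absorbs some of that variance into η and ρ.
- The conditioned race and bias models drop trials whose predecessor drew
  no valid response (the stratum index is undefined there).
- BCa p-values for mediation paths use the percentile-of-zero inversion;
  with very small bootstrap counts they are coarse.
- The mixed model's crossed random effects are fitted as variance
  components within a single encompassing group, which is slower than a
  dedicated crossed-effects sampler and can be singular on tiny cohorts
  (flagged, not raised).
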