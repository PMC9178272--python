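# Methods

This note documents the statistical model behind `ymi`, the conventions
and defaults it commits to, what the synthetic generator does and does
not emulate, and the numerical choices a user auditing results should
know about.

## Per-fly measures

A fly's raw observable is an ordered sequence of binary turns
(1 = right). Three statistics are derived per fly:

- **Turn bias** `p̂` — the fraction of right turns, the maximum-likelihood
  plug-in estimate with no continuity correction. Raw fractions are kept
  deliberately: for a fly making `n` turns only the `n + 1` fractions
  `k/n` are possible, and smoothing them would destroy the discreteness
  structure visible in joint scatter plots of bias magnitude vs. turn
  count.
- **Number of turns** `n` — sequence length; always defined (0 for an
  inactive fly).
- **Switchiness** `S = A / [(n − 1) · 2 p̂ (1 − p̂)]`, where `A` counts
  adjacent unequal pairs. The denominator is the expected alternation
  count for i.i.d. Bernoulli(`p̂`) turns, so `S` measures serial
  dependence on a scale where the binomial null sits at 1, streaky flies
  below, over-alternators above. `S` is undefined when the normalizer
  vanishes (`p̂ ∈ {0, 1}` or `n < 2`) and is carried as an explicit
  missing value — such flies are retained, and analyses of `S` drop
  missing values pairwise with exclusion counts logged. An optional
  minimum-turn filter exists but defaults to 0 (off), so grand analyses
  use every fly.

Two normalizer variants are defensible a priori (`n` vs `n − 1`;
conditioning on the observed count or not). The implemented form has
`E[S | k right turns] = n/(n − 1)` exactly under the null (uniform
arrangement of `k` successes), hence mean `S → 1` as `n` grows for any
fixed bias — the calibration property the test suite enforces, which any
correct variant must satisfy. Turn *clumpiness* (timing burstiness) is
deliberately not computed; timestamps are carried through but unused.

## Distribution characterization

- **Standardized moments.** Order 1 is the mean and order 2 the variance;
  orders ≥ 3 are `(1/m) Σ ((x − x̄)/s)^k` with `s` the sample SD
  (ddof 1). Kurtosis is reported non-excess (Gaussian = 3). Affine
  invariance holds for the standardized orders; odd orders flip sign
  under reflection.
- **Bootstrap.** The resampling unit is the fly. `B` = 1,000 replicates
  by default, equal-size draws with replacement, replicate stream fully
  determined by the seed. The 95% CI is point estimate ± 2 × SD of
  replicate values (true coverage of a ±2σ interval is 95.45%, verified
  at 95–96% in the suite's calibration tests). Replicates on which a
  statistic is undefined are recorded as missing, excluded and counted,
  not silently dropped.
- **Moment panel.** All orders (default up to 20) are computed on one
  shared stream of resamples, so the panel is internally consistent. The
  significance measure is |bootstrap mean| / bootstrap SD, with ≥ 2 the
  conventional p ≈ 0.05 threshold against zero.
- **Subsample stability.** For each requested fraction a single random
  subset is drawn without replacement (seeded) and the panel recomputed;
  a repeat-count parameter allows dispersion studies, but the default
  single draw mirrors how such curves are usually displayed. The point of
  this analysis is that estimability of high orders depends on the
  underlying distribution, not just `n`: a bounded sample retains a
  significant 12th moment through 10-fold subsampling where a log-normal
  sample of equal size has already lost it.
- **KDE.** Gaussian kernel, Silverman's rule by default, bandwidth
  exposed as an absolute SD. No boundary correction is applied at the
  edges of bounded supports (e.g. bias at 0/1); this is a documented knob
  rather than a hidden behavior, and matters only within a bandwidth of
  the bounds. The optional CI band is the per-grid-point ±2 SD of
  bootstrap replicate densities at fixed bandwidth.
- **Gaussian fit.** True ML (ddof 0). At cohort scale the ddof choice is
  irrelevant; it is pinned so that the two-point example `{0, 2} → (1, 1)`
  is exact.

## Variability analyses

- **Levene transform.** Deviations use the *group mean*, not the median:
  the measures here are near-symmetric, and the mean-based transform is
  the one whose one-way OLS F-statistic equals the classical Levene test
  exactly (verified to 6 decimals against an independent implementation).
  Singleton groups carry no spread information and are excluded with a
  warning. The default grouping for the stored `lev_*` columns is
  genotype × condition, so downstream models can add further predictors.
- **Coefficient of variation** is σ/μ with sample SD (ddof 1); groups
  below the minimum size (default 2) are excluded and non-positive means
  flagged (CV is meaningless on a non-positive scale).
- **Metadata linear model.** OLS with treatment (reference-level) coding
  of categoricals, built explicitly via dummy columns rather than a
  formula engine so that rank deficiency can be diagnosed by
  rank-revealing QR and reported with the names of the aliased columns
  (the canonical failure: a date column jointly determined by the other
  covariates). The date column is therefore excluded from the default
  predictor set; eyeColor is excluded as a recode of genotype.
- **Genotype enrichment.** Each genotype's mean is tested against the
  grand mean with a two-sided one-sample t-test, giving one nominal
  p-value per genotype (uniform under the null — a property the suite
  checks by Kolmogorov–Smirnov). The count below α is then tested
  against Binomial(N, α) one-sided: "enrichment" asks specifically
  whether there is an excess. A coefficient-based test (G − 1 contrasts
  against a reference level) was the main alternative; the per-genotype
  test was chosen because it yields exactly one p-value per genotype and
  no arbitrary reference line.
- **Paired effects.** For genotypes present in both conditions,
  `effect_pct` is 100 × the mean over genotypes of
  `(cv_treatment − cv_control)/cv_control` — per-genotype relative
  changes, not a change of pooled means, because the pairing is the
  design's unit; a pooled aggregation is available by option.
  Significance is a two-sided paired t-test on the CV pairs. Swapping the
  condition labels preserves the p-value exactly and maps the effect to
  approximately `−e/(1 + e/100)`. When the paired CVs are identical the
  t-statistic is defined as 0 with p = 1 (no evidence of any effect)
  rather than NaN. Temperature contrasts first fold 22 → 23 °C and
  32 → 33 °C, since experiments run at either label belong to the same
  arm. No multiple-testing correction is applied anywhere; all p-values
  are nominal by design.

## Synthetic cohorts

Each fly gets latent parameters: bias `p` from a Beta distribution
parameterized by mean and SD (mixture optional; SD 0 gives a point
mass), serial correlation `ρ = 1 − S*` with the target switchiness `S*`
drawn normal and clipped into the admissible range
`ρ ∈ (−min(p, 1−p)/max(p, 1−p), 1)` (clip counts reported), and a
negative-binomial turn count. Turns are emitted by the two-state Markov
chain `P(R|R) = p + ρ(1−p)`, `P(R|L) = p(1−ρ)`, whose stationary
marginal is `p` and expected alternation rate `2p(1−p)(1−ρ)`, so mean
switchiness ≈ `1 − ρ`; the suite verifies this map on a (p, ρ) grid to
±0.03.

Defaults emulate study-scale conditions: bias mean 0.496 and SD 0.15
(slight left bias, realistic across-fly spread), switchiness mean 1.0
with SD 0.1, turn-count mean 435 (a cohort of ~1.8 × 10⁵ flies making
~8 × 10⁷ choices averages ~435 turns per fly) with dispersion 2 for a
right-skewed, overdispersed activity distribution. Group designs cross
genotype × condition × sex × temperature; per-group SD multipliers
(keyed by genotype, genotype–condition pair, or condition-/sex-wide)
inject known variability effects, with turn-count SD factors realised by
re-solving the negative-binomial dispersion at fixed mean.

The cohort table's measures are always computed from the emitted
sequences by the measures module — never assigned from the latent truth —
so generator-based tests close the full loop. A separate exact-marginal
sampler exists for the serially independent case only (measured
handedness is exactly Binomial(n, p)/n when ρ = 0), used where studies
need many large cohorts and only the bias column; it refuses to run when
ρ ≠ 0 and leaves switchiness missing.

What the generator does **not** emulate: turn timing (optional times are
i.i.d. exponential gaps, a placeholder with no physiological content);
the correlated sub-population seen in real data's switchiness–bias joint
distribution (injectable via a mixture, but its parameters are user
guesses); real metadata confounding structure (experimenter, tray, box
and date are filled with constants, so metadata-model recovery tests
exercise the machinery, not realistic imbalance). Tests passing on
synthetic cohorts therefore validate the estimators' calibration and
recovery properties, not claims about any real dataset.

## Problem sizes and determinism

Simulation-backed checks run at sizes chosen to make Monte-Carlo error
small relative to the tested tolerance while keeping the full suite
around a minute: 10,000 flies × 1,000 turns for the switchiness
calibration (SEM ≈ 0.0003 against a ±0.01 band), 10⁵ samples for
moment closed forms, 20 genotypes × 400 flies/condition for effect
recovery, 200 replicate designs for false-positive calibration, and
10⁵-fly cohorts for the grand-mean analyses. All randomness flows
through explicit integer seeds (numpy `SeedSequence` for derived
streams); identical spec + seed reproduce cohorts and reports
bit-for-bit.

## Known limitations

- Only mean-based Levene modelling and OLS: no mixed-effects or Bayesian
  variance models, no interaction terms in the metadata model (main
  effects only).
- KDE has no boundary correction; densities within one bandwidth of a
  bound are biased downward.
- The bootstrap CI convention (±2 SD) is symmetric by construction and
  can be slightly off for strongly skewed statistics at small n;
  percentile intervals are not implemented because the ±2 SD convention
  is the package's fixed reporting standard.
- The switchiness normalizer uses the fly's own estimated bias, so at
  very small n the statistic is noisy and weakly biased
  (E[S] = n/(n−1) under the null); no small-sample correction is
  applied.
- `read_cohort` validates row-level invariants but does not enforce the
  controlled vocabulary of the condition column (free-text labels pass
  through), only sex and eye-color levels.
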