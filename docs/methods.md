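# Methods

This note records the statistical conventions, the generative model behind
the synthetic studies, and the design choices made where more than one
defensible convention exists.

## Display complexity

A focal sequence is an ordered list of timestamped posture events from a
finite repertoire (nine ritualized postures for the flamingo group display),
recorded over a fixed 300-second window (half-open, `[0, 300)`, 0-based
times).  Scores:

- **Richness** `R`: number of distinct postures occurring at least once
  (`1 ≤ R ≤ 9`).
- **Versatility** `V`: by default the *change count* — the number of
  adjacent event pairs with different postures.  Adjacent duplicate events
  (an observer re-logging a held state) are collapsed before counting, so a
  re-logged state never counts as a transition; collapsing happens at
  scoring time, not at parse time, so raw logs are preserved.  An
  alternative reading, *distinct ordered transitions* (the number of unique
  ordered posture pairs), is available via `mode="distinct-ordered-transitions"`.
  The field wording "number of transitions between different postures"
  admits both; change count is the default because observed versatility
  ranges of 2–17 within a 5-minute bout, and the song-complexity literature
  this metric descends from, count transition events.  The default is a
  documented choice, not a claim about any particular study's coding.
- **SDC** `= R × V`, an exact integer identity enforced by the score type.
  A monotone sequence scores `V = 0` and hence `SDC = 0`; no lower cutoff
  is imposed.

Event logs are two-column (time, code) delimited text, comma or tab, header
optional, time in seconds or milliseconds.  An optional final row with code
`EOF` marks the end of the observation and sets the observation span
(event-recorder convention); without it the last event time is used as the
span.  `filter_complete` keeps only sequences whose span reaches the full
window — interrupted-but-resumed displays are not spliced; a sequence must
be one continuous window.  Wall-clock times are rebased to the window start
only when they fall outside it, so writing and re-parsing a valid log is the
identity.

## Standardization

Every predictor is centered and divided by **two** sample standard
deviations (Gelman's rule), giving each column mean 0 and SD 0.5.  This
makes the slope of a numeric predictor directly comparable to the contrast
of a 0/1 binary predictor.  The quadratic age term is squared *first*, then
standardized as its own column.  Binary columns (sex, year) are standardized
by the same rule as numeric ones — a uniform convention, deliberately
simpler than packages that leave binaries at ±0.5 shifts only; the
difference is a scale factor absorbed by the coefficient.  Interactions are
products of the standardized main-effect columns.  The per-column
(mean, SD, min, max) are retained in a scaling record so new data (e.g. an
age grid for prediction) are transformed identically.

## Model set, fitting, AICc

The full display model is
`age + age² + sex + group_size + hour + date + year + age:sex + date:year`;
the breeding model is `sdc + sex + age + age²` with a binomial(logit)
family.  The candidate set is every subset of the full term list that

1. respects marginality (age² only with age; an interaction only with both
   mains), and
2. avoids forbidden collinear pairs — by default `{group_size, date}`,
   because display-group size and season date covary strongly in the field.
   The exclusion list is configuration; observed correlations are reported
   but never trigger automatic exclusion.  A `max_terms` cap is available
   for the 10:1 subjects-to-predictors rule of thumb.

The intercept-only model is always included (112 display candidates, 9 for
breeding).  Fits are maximum likelihood: OLS for the gaussian family (its
log-likelihood uses the ML residual variance, matching R's `logLik(lm)`) and
IRLS for the binomial.  Parameter counts: gaussian `k` = intercept + slopes
+ residual variance; binomial `k` = intercept + slopes.  This is the only
counting consistent with the published model-selection arithmetic the test
suite verifies.  A binomial fit showing separation (non-convergence,
exploding coefficients, fitted probabilities at 0/1) is flagged and excluded
from ranking and averaging with a logged warning.  A gaussian fit with ~zero
residual variance has a divergent likelihood; it is flagged `degenerate` and
its log-likelihood capped at `+inf` rather than erroring.

`AICc = −2 logL + 2k + 2k(k+1)/(n − k − 1)`, undefined (an error) when
`n ≤ k + 1`; `n` is the number of rows actually modelled (the full cohort
for display responses, the monitored single-season cohort for breeding).
Akaike weights are `exp(−Δᵢ/2)` normalized over whatever set is supplied.
Ties in AICc rank are broken by fewer parameters, then lexicographic term
order, so rankings are deterministic.

## Model averaging (zero method) and prediction

Over the top set (ΔAICc ≤ 2, weights renormalized to sum to 1):

- estimate: `β̄ = Σ wᵢ βᵢ`, with `βᵢ = 0` in models that omit the term
  (the "full average" — shrinks uncertain terms toward zero);
- unconditional SE: `Σ wᵢ √(varᵢ + (βᵢ − β̄)²)`, again with `varᵢ = βᵢ = 0`
  where the term is absent;
- CI: `β̄ ± 1.96·SE` (normal multiplier — a fixed, documented convention;
  published CIs built with other multipliers are not reverse-engineered);
- importance: sum of (renormalized) weights of the top models containing
  the term.

Prediction over an age grid holds date fixed — day 94 of the season
(February 3, with November 1 as day 0) by default — standardizes the grid
with the stored scaling record, applies the coefficient vector, and
inverse-logit transforms for binomial responses.  Ages outside the fitted
range are returned flagged `extrapolated` rather than refused.

## Rank tests

The Wilcoxon–Mann–Whitney statistic is reported in the R convention
(`W` = Mann–Whitney U of the first sample); the signed-rank statistic is the
positive-rank sum.  Exact p-values (enumeration) are used when the data are
tie-free and `min(n) ≤ 12`; otherwise a normal approximation with
tie-corrected variance and **no** continuity correction.  Without the
correction the approximation can sit up to ≈0.03 from the exact value at
n≈8–12 (worst near p = 0.5), which is the price of the simpler documented
convention.  Degenerate inputs (all values identical; all differences zero)
return p = 1 with a flag instead of erroring.

## Randomization test of assortative mating

The statistic is the mean absolute within-pair difference of an attribute
(age, or SDC predicted from age through the fitted `age + age² + date` model
with date fixed at day 94, so predicted SDC is a pure function of age).
Each of `n_sim` (default 1000) simulations permutes one sex's attribute
vector against the other — re-pairing within the observed members, identity
permutation allowed, no derangement forced.  The null band is the
(2.5th, 97.5th) percentile interval of the simulated means (linear
interpolation between order statistics).  Verdicts: `outside-low` (observed
difference smaller than random ⇒ homogamy), `inside`, `outside-high`.  No
p-value is attached beyond the interval position.  The test is invariant to
which sex is permuted, and fully reproducible given a seed.

## Synthetic studies

The generator emulates the study conditions the analysis assumes, with one
sequence per individual (cross-sectional design; no within-individual
repeatability is modelled):

| element | default | rationale |
| --- | --- | --- |
| cohort | 100 individuals, 50 F / 50 M | field sample size |
| ages | M uniform 4–34 yrs, F uniform 5–37 yrs | observed per-sex ranges |
| dates | uniform day 0–151 (Nov 1–Mar 31) | courtship season |
| group size, hour | uniform 9–130; 8:00–17:00 | observed ranges; daylight |
| monitored cohort | 56 individuals in the later season | breeding data available for one season |
| pairs | 21, both members drawn from the cohort | ringed-pair sample size |

Latent quality
`q = q0 + q_age·age + q_age²·age² + q_date·date + N(0, σ_q)` with defaults
`(−0.25, 0.14, −0.0035, 0.0035, 0.30)`: concave in age with the peak at
age 20 (q_age / −2 q_age² = 20), rising over the season.  Sequences are
first-order Markov chains over the repertoire: event count
`Poisson(20) + 1`; at each step the bird switches posture with probability
`s(q) = logit⁻¹(logit(0.30) + 0.70 q)` to a uniform choice among an
accessible set of `m(q) = clip(2 + round(3.5 q), 2, 9)` postures (a random
repertoire subset per sequence); event times are an ordered uniform sample
on the window.  Under this process `E[V] = E[events − 1]·s(q)` exactly
(verified by simulation in the tests), and `R ≤ m(q)`.  These coefficients
were fixed once so that scored richness falls in 2–8, versatility in 2–17
and SDC in 4–136 for ≥90% of sequences — the published score ranges — and
give a cohort mean SDC near 55 with roughly 1.7–2× higher SDC at the age
peak than at the extremes.

Breeding status is `Bernoulli(logit⁻¹(γ0 + γ1·z))` on 2-SD-standardized
SDC, defaults `γ0 = −1.2` (prevalence ≈ 0.23, i.e. ≈13 breeders of 56) and
`γ1 = 1.4` (the magnitude of the published standardized SDC effect).  Pairs
are matched on the deterministic age-quality curve: each sex's individuals
are ordered by `ρ·(standardized rank) + (1 − ρ)·N(0,1)` and matched in
order, so `ρ = 1` is exact rank-matching on predicted display complexity,
`ρ = 0` uniform random pairing; the default `ρ = 0.9` produces the
SDC-homogamy signal at `n = 21` pairs in the majority of replicates.

Everything is driven by one `numpy` Generator: the same (config, seed)
reproduces a study bit-for-bit.

**What passing tests on this generator do and do not show.**  The generator
reproduces the *statistical structure* the pipeline assumes — a concave
age–quality profile expressed jointly in richness and versatility, a
logistic SDC–breeding link, rank-based pair assortment — but not field
realism: no diurnal or social dynamics, no observer error in posture coding,
no within-individual variation, independence between individuals.  Green
tests certify the machinery (scoring, selection arithmetic, averaging,
calibration of the randomization test), not any empirical claim about real
displays.

## Problem sizes used in the test suite

Simulation-based checks use: 500 replicate experiments (each with a
1000-draw null) for the randomization test's type-I error at ρ = 0 and power
at ρ = 0.9; 40 replicate cohorts of n = 100 for recovery of the quadratic
age effect (best model contains age + age², averaged age² negative);
2000 sequences for the analytic change-count expectation; exhaustive
enumeration oracles for rank tests at n ≤ 8 and 3-pair re-pairing.  These
sizes give Monte-Carlo standard errors comfortably below the asserted
margins while keeping the default suite fast.

## Known limitations

- Gaussian GLMs on SDC ignore the score's discreteness and mild
  heteroscedasticity, as is conventional for this analysis; residual checks
  are the user's responsibility.
- The zero-method SE uses the classic unconditional-variance formula (no
  revised small-set correction).
- Age and age² are standardized, not orthogonalized; their collinearity
  inflates both coefficients jointly (their sum describes the curve; the
  curve's peak and curvature sign are stable and are what the tests assert).
- The randomization null permutes within the observed pair members; mates
  drawn from a wider unobserved pool are not modelled.
- The exact/approximate Wilcoxon switch at min(n) = 12 is a convention;
  near the boundary the two paths can differ by up to ≈0.03 in p.
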