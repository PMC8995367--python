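# Methods

This note documents the models, estimators and design choices behind
`metaconf`, and what its simulation-based validation does and does not
establish.

## Task and data model

One trial of the confidence forced-choice paradigm contains two consecutive
contrast discriminations (test patch vs. a 22% standard; test contrasts
13–31% in 3% steps, i.e. signed differences Δ ∈ {−9, …, +9}) followed by a
forced choice of which decision the observer is more confident about.  A
session is 420 trials in 6 blocks of 70; each of the 7 levels appears
exactly 60 times per task position, with the two positions counterbalanced
independently (method of constant stimuli).  Sessions are stored one row
per trial; analyses that operate on individual decisions use a long view
with two rows per trial carrying the 0/1 confidence code (1 = selected as
more confident).

Responses faster than 100 ms or slower than 3000 ms are treated as
anticipatory or delayed.  The bounds are applied to *RT analyses only*:
decisions with out-of-bound RTs still enter psychometric and confidence
analyses.  The filtering paragraph of the original analysis introduces the
bounds in the RT context only, and with exclusion rates below 1% either
reading is numerically minor; scoping to RT analyses is the conservative
choice.  Laterality of the test patch is generated and stored but not
analysed.

## Psychometric fitting

Each confidence set is reduced to per-level counts (Δ, n, k) with k the
"test higher" reports, and fitted with

p(Δ) = λ/2 + (1 − λ) Φ((Δ − μ)/σ)

The symmetric-asymptote form (guess rate = λ/2) is appropriate because the
left/right report is recoded as "test higher"; errors at both tails are
exchangeable.  Estimation is penalized maximum likelihood: binomial
log-likelihood plus a Beta(1.5, 20) log-density penalty on λ, bounds
λ ∈ [0, 0.1], σ ∈ [0.1, 100] % contrast, μ within the level range widened
by half a span on each side.  The penalty keeps λ identifiable on 7-level
data without pinning it to zero.  Optimization runs L-BFGS-B with analytic
gradients in (μ, log σ, λ) from a fixed 6-point start grid, so fits are
deterministic.  Tests verify oracle equivalence against dense grid searches
of the same objective.

Degenerate data are reported, not hidden: responses with no slope
information (all "higher" or all "lower") return σ at the upper bound;
perfectly separated data return σ at the lower bound with μ at the midpoint
of the empty interval; both warn and mark the fit as non-converged.
Goodness of fit is the deviance D = 2 Σ [k ln(k/(np̂)) + (n−k) ln((n−k)/(n(1−p̂)))]
with 0·ln 0 = 0; a fitted probability of exactly 0/1 against a discordant
count yields +∞.

This estimator is a deliberate, deterministic stand-in for Bayesian
psychometric toolboxes: point estimates agree closely for well-behaved
data, but exact reproduction of numbers fitted with a particular Bayesian
toolbox is not claimed.

## Confidence modulation index

CMI = 100 (s_c − s_u)/s_u from the two fitted sensitivities (1/σ).  Being a
proportional measure it is arcsine-square-root transformed before
inferential statistics.  The classical transform is undefined for negative
CMIs, which occur by sampling noise; the package uses the signed extension
sign(c)·arcsin(√(|c|/100)), which is odd, strictly monotone, and reduces to
the classical transform for non-negative values.  Group statistics are
computed on raw and transformed values side by side.  Outliers are flagged
once, on untransformed CMIs over the pooled sample, with Tukey fences
(1.5 × IQR beyond the quartiles, quartiles by linear interpolation);
flagged participants are dropped from group statistics but retained,
flagged, in the per-participant tables.

## Generative observer

Per decision with signed difference Δ, internal evidence is
e ~ N((Δ − bias)/σ_s, 1); the report is the sign of e, replaced by a fair
coin with probability `lapse`.  Confidence evidence is c = |e| + N(0, σ_c)
— the standard SDT distance-from-criterion rule with additive confidence
noise as the single inefficiency parameter (criterion jitter or confidence
lapses are not modelled) — and the decision with larger c is chosen.
σ_c = 0 defines the idealized observer.  RTs follow the exponential model
below with the generative S = (Δ − bias)/σ_s and the realized confidence
code, plus N(0, rt_noise_sd) noise truncated at the 100 ms bound.

Expected confidence-choice probability maps P(choose decision 1 | Δ₁, Δ₂,
decision combination) are computed by Gaussian quadrature over the
bivariate evidence density, with each axis split at the criterion where |e|
has a kink (96 Gauss–Legendre nodes per axis; for σ_c = 0 the inner
integral is analytic in Φ).  Agreement with Monte-Carlo simulation is
within three standard errors at 10⁵–10⁶ samples, and the aggregate map
satisfies P(a, b) + P(b, a) = 1 to ~1e−14.  `expected_cmi` computes the
large-sample limit of the pipeline's CMI estimate: expected set proportions
(with the competitor level marginalized uniformly over the design) are
fitted with the pipeline's own estimator.

## Cohort generator

The default cohort emulates the study conditions the package targets:
30 observers per age group; sensory noise σ_s ~ truncated normal (older:
6.0 ± 1.5, younger: 4.2 ± 1.0 % contrast), giving unsorted-sensitivity
group gaps of d ≈ 1.4.  Confidence efficiency is parametrized on the CMI
scale: each participant draws a latent target CMI (older: 23.04 ± 15.1,
younger: 31.21 ± 9.0, the published group means with SDs recovered from the
printed SEMs), and σ_c is obtained by inverting a cached quadrature table
of expected CMI over (σ_s, σ_c); targets beyond the achievable range are
clipped to its borders.  RT parameters: α older 524 ± 165 ms, younger
438 ± 135 ms; β = −80 ± 25 ms (negative: slower near the PSE under the
printed model); γ = 72 ± 20 ms (confident decisions ~36 ms faster on
average against C̄ = 0.5); trial noise SD 150 ms.  Cognitive scores use the
published group means/SDs (DSST, TMT-B, VST-C, LPS-3, digit span), with
timed scores generated on an inverted scale.

`ef_link` (default 0.4) is the target *pooled* Pearson correlation between
the EF composite and the **measured** CMI.  The construction is a Gaussian
copula: the four EF measures load (λ = 0.8) on a within-group common
factor whose correlation with the latent CMI trait is solved analytically
from the pooled-moment equations, including (a) the between-group
contribution of the group gaps in EF and CMI and (b) inflation for the
single-session CMI estimation noise, entered as the calibration constant
`cmi_noise_sd` = 14 CMI points (the measured SD of one session's CMI
estimate under the package's fitter at the design's n, averaged over
typical observers of both groups).  Digit span is generated independently
of the trait.  A calibration test (200 cohort replicates) verifies that
the mean recovered CMI–EF correlation is within ±0.05 of the target; it
centres near 0.38–0.40, with the residual shortfall due to clipping and
heteroscedastic estimation noise.  An `ef_link` demanding a within-group
factor correlation outside (−1, 1) raises before simulation.

What the generator does *not* emulate: sequential/learning effects, lapses
of attention correlated over time, non-Gaussian evidence, RT distributions'
skew (only cell medians are analysed), integer-valued cognitive scores, or
criterion drift.  Passing tests therefore validate the estimators and the
pipeline logic under the stated generative assumptions, not the full
richness of empirical data.

## Response-time model

Per confidence set, decisions surviving the RT filter are grouped by the 7
signed levels; each cell carries the median RT (standard order statistic)
and the mean confidence code C (chosen set: C ≡ 1; unsorted set: the
fraction chosen).  S is computed from the *unsorted-set* psychometric fit
for both sets, so both share one normalization — the unsorted fit uses all
data and is the stable choice.  The model RT(S) = α − β e^{−S²/2} − γC is
fitted by least squares over all (≤ 14) cells jointly, because a per-set
fit cannot identify γ within the chosen set where C is constant.  The model
is linear in (α, β, γ), so the least-squares problem is solved exactly via
`numpy.linalg.lstsq` — deterministic and globally optimal, verified against
a 50³ parameter-grid oracle.  Cells are unweighted; under this
parametrization "slower when difficult" corresponds to β < 0 and "faster
when confident" to γ > 0.  Designs lacking variation in e^{−S²/2} or in C
raise an identifiability error naming the missing variation.

## Statistics layer

EF composite: DSST and LPS-3 are z-scored as-is, TMT-B and VST-C negated
first (higher = better), z-scores over the pooled sample; EF is the mean of
the four.  Mixed 2×2 ANOVAs (between: age group; within: confidence set)
use classical sums of squares via `pingouin.mixed_anova`, reported with
partial η²; an independent hand sums-of-squares oracle and the F = t²
identity (with the ANOVA's error df) are verified in tests.  Two-sample
comparisons gate Student vs Welch on Levene's test (mean-centred, α =
0.05); Cohen's d uses the pooled SD (independent) or the SD of differences
(paired).  Correlations are Pearson; the first-order partial correlation
controlling a binary group code uses the standard formula (equivalently,
the correlation of within-group-centred variables) with n − 3 df.
Confidence intervals are 95% percentile bootstrap from 2000 resamples,
participant as the resampling unit, stratified by group for between-group
contrasts, all seeded.  p-values are two-sided and unadjusted.  Under null
simulations the gated t-test's type-I error is calibrated at 5% ± 1.5%.

## Problem sizes and numerics

Validation runs at desk scale: psychometric oracle grids of ~10⁴ points,
100 sessions for σ_s recovery (median error < 15%), 200 cohort replicates
for the EF-link calibration, 10⁵–10⁶ Monte-Carlo draws per quadrature
check, 1000 null replicates for type-I calibration.  The expected-CMI
table (10 σ_s × 14 σ_c quadrature evaluations) is computed once per
process and cached.  Quadrature uses Gauss–Legendre panels over ±8.5
evidence SDs split at the criterion; psychometric optimization tolerances
are scipy's L-BFGS-B defaults; RT fitting is closed-form.  Ties in the
confidence comparison (zero-probability events under the continuous model)
are broken by a fair coin.
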