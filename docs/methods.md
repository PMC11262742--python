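# Methods

This note records the statistical content of `claimscreen`: the screening
rules, the mixed model and its estimation, the synthetic-data generator and
its calibration, numerical conventions, and known limitations.

## Data model

The atomic record is a centre-day: `(centre_id, category, date, n_tests,
n_positive)` with `0 ≤ n_positive ≤ n_tests`, `(centre_id, date)` unique and
the category constant per centre. Duplicated centre-days are a *hard error*,
not silently aggregated — duplicate billing rows are themselves a fraud
signal and must surface to the analyst.

Days with `n_tests = 0` carry no information for any screen: a zero has no
leading digit, contributes nothing to the mean daily volume, and leaves the
positivity offset `log(n_tests)` undefined. Such days are therefore excluded
from digit histograms, from `mean_daily_tests`, from the ≥ 30-day
eligibility count, and from the model rows. "Active day" throughout means a
day with at least one invoiced test.

Calendar weeks are consecutive 7-day blocks anchored at the study window's
start date (1-based), not ISO weeks; the reference window
2021-04-08..2022-08-28 spans 508 days = 73 weeks.

## Screening rules

**High volume.** Within each category, centres are ranked by mean daily
tests over active days and the top `ceil((1 − q) · n_eligible)` are flagged
(default q = 0.90). The count rule — rather than an interpolated quantile
threshold — is used because it is well defined under ties and reproduces
per-category cohort sizes exactly (60/390/457 eligible centres → 6/39/46
flags). Ties are broken by (score descending, centre id ascending); the
cutoff count is computed in exact rational arithmetic because binary
floating point would turn 0.1 × 390 into 39.000000000000004 and ceil it
to 40.

**Digit screens.** Eligibility requires ≥ 30 active days (the digit
distribution of a handful of days is not interpretable); ineligible centres
remain in the output as eligible = false and are never flagged. For each
eligible centre the Pearson χ² of the leading-digit counts against Benford's
`p_d = log₁₀(1 + 1/d)` (first-digit screen) or of the last-digit counts
against uniform 0.1 (last-digit screen) is computed, and the top
`ceil(0.10 · n_eligible)` centres by χ² are flagged. The χ² is a ranking
score, not a calibrated p-value, so no small-expected-count correction is
applied. A separate diagnostic (`low_variance_centres`) lists centres whose
daily counts take fewer than five distinct values — data too rigid for digit
forensics — as a warning rather than an exclusion, since low variance is a
documented caveat of the method, not a filter of the screening rule.

**Low positivity.** Daily positives are modelled as

    n_positive ~ Poisson(μ),   log μ = log(n_tests) + β₀ + β_cat + u_j + v_k

with crossed random intercepts `u_j ~ N(0, σ_u²)` (centre) and
`v_k ~ N(0, σ_v²)` (calendar week, absorbing incidence changes over time),
and the category fixed effect with doctor's/dentist's offices as the
(arbitrary, documented) reference level. The week enters as a random — not
fixed — effect so that 73 weekly levels are shrunk rather than freely
estimated.

*Estimation.* The marginal likelihood is maximised under the Laplace
approximation. Inner step: damped Newton on the joint penalised
log-likelihood of `(β, u, v)` (sparse design matrix, dense Cholesky of the
~1000-dimensional Hessian), i.e. fixed effects are profiled at the joint
mode. Outer step: Nelder-Mead on `(log σ_u, log σ_v)` with the inner mode
warm-started. The Laplace objective is the joint log density at the mode
plus `(q/2)·log 2π − ½·log det S`, where `S` is the random-effect block of
the negative Hessian. Adaptive quadrature is not available for crossed
designs; Laplace is the standard estimator there. Cross-checks: the fit
agrees with R `lme4::glmer` to ~3×10⁻⁴ in both σ's and ~0.02 in the EB
modes, and with an exact adaptive 50-node Gauss–Hermite marginal ML to
< 10⁻³ in σ̂_u on a centre-only toy. (Plain, non-adaptive Gauss–Hermite is
*not* a valid oracle at high information: the integrand spike falls between
its nodes.)

*Conditional standard deviations.* `se(û_j)` comes from the diagonal of the
inverse of the full random-effect Hessian `S⁻¹`, which retains the coupling
between centre and week blocks. (`lme4`'s `condVar` drops that coupling and
returns smaller per-factor values; the coupled version is the more accurate
conditional covariance under the same approximation.)

*Flag rule.* One-sided empirical-Bayes z-test: flagged iff
`û_j / se(û_j) < Φ⁻¹(α)`, default α = 0.05, exposed in configuration. The
original pilot's exact significance criterion was described only in an
unpublished technical report, so this rule is the package's own documented
operationalisation; its reported flag count (88 of 907 centres) is
consequently not treated as a reproducible target. Note the rule tests
H₀: u_j = 0 per centre; with genuine between-centre heterogeneity it
correctly flags the truly-low tail and the flagged fraction will exceed α —
only under a homogeneous population does the flagged fraction calibrate
to ≤ α. Rows with `n_tests = 0` are dropped; a centre with no model rows is
ineligible, as is one with a degenerate (zero) conditional sd. A boundary
estimate σ̂ ≈ 0 produces a warning, not an error; outer-optimiser failure
raises a convergence error carrying the iteration trace, and the pipeline
then degrades to a three-detector run with a distinct exit code.

## Combination and evaluation

Flags combine by `any` (statistical conspicuousness: at least one screen)
or `at least k`; a centre is eligible for a combination if eligible under at
least one member. Crossing flags with conventional suspicion gives the 2×2
agreement table (a, b, c, d); the reported metrics are

    positive overlap  = a/(a+b) · 100     (sensitivity analogue)
    negative overlap  = d/(c+d) · 100     (specificity analogue)
    incremental share = c/(c+d) · 100     (= 100 − negative overlap, exactly)

and, against post-investigation outcomes, the incremental predictive
validity = (newly flagged and corroborated) / (all flagged) · 100.
Percentages are carried as exact rationals and rounded half-up to one
decimal only for reporting, which reproduces published one-decimal figures
bit-for-bit from their integer counts.

Centres with a missing suspicion label (in the pilot: pharmacies, which are
supervised by a different authority) are handled by a configuration switch:
`treat_as_unsuspected` (default — matches how published tabulations carry
them in the not-suspected margin) or `exclude` (drop and report the count).

## Synthetic claims generator

The generator emulates the observable structure of the pilot data; it is
the package's test bed, not a reconstruction of any confidential microdata.

**Volumes.** Daily test counts per category follow a discretised log-normal
(minimum 1), chosen over Poisson because real daily volumes are heavily
over-dispersed (published range 1–37,373) and a wide log-spread is exactly
what makes Benford behaviour emerge in honest centres. Calibration matches
the published per-category median *and* mean simultaneously:
μ = ln(median) and σ² = 2·ln(mean/median), giving (μ, σ) of (4.16, 1.02)
for pharmacies (median 64, mean 108), (1.61, 1.70) for practices (5, 21)
and (4.75, 1.02) for private centres (115, 194). The total log-variance is
split evenly into a between-centre size component and within-centre
day-to-day variation, so centres differ persistently in size and the volume
screen is non-trivial.

**Positivity.** Per-day probability
`p = expit(logit(p_cat) + u_c + v_k)` with category levels 2.44% / 2.75% /
1.95% (published category rates), centre heterogeneity sd 0.3 and weekly
effects drawn N(0, 0.3) on the log-odds scale (or a user-supplied weekly
curve). Positives are binomial given the day's tests.

**Activity.** Centres start at a uniformly drawn offset in the first half of
the window; a quarter are short-lived (5–60 day spans); open-day
probabilities are 0.70/0.25/0.80 by category. Under the defaults this
leaves roughly a quarter of centres below the 30-active-day digit-screen
eligibility, matching the pilot's proportion of excluded centres.

**Fraud behaviours**, applied in the fixed order inflation → fabrication →
rounding (rounding must act last to control the final digit), with
suppression acting on the positivity probability:

| behaviour | default | effect |
|---|---|---|
| volume_inflation | ×8 | multiplies expected daily volume before the draw |
| fabrication | 480–520 | replaces the volume draw by a uniform integer in the band |
| digit_rounding | base 5 | rounds the final volume to the nearest multiple (min = base) |
| positivity_suppression | ×0.25 | multiplies the positive probability before the binomial draw |

Default prevalence is 5% per behaviour, independently. Effect sizes are
deliberately strong — the generator's purpose is separable ground truth for
detector testing, and no published quantitative description of fraudulent
behaviour magnitude exists to calibrate against.

**Labels.** Conventional suspicion and corroboration are two independent
coins conditioned on the centre's true fraud status
(P(suspected|fraud) = 0.45, P(suspected|honest) = 0.025,
P(corroborated|fraud) = 0.85, P(corroborated|honest) = 0.10). With default
prevalences this yields ≈ 93 suspected centres out of 907, the pilot's
order of magnitude, and makes all agreement metrics non-degenerate.

**Reproducibility.** All randomness derives from one root seed via
substreams keyed by (category, within-category index), so identical configs
give byte-identical output files and adding a centre to one category never
shifts any other centre's draws.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: day-of-week and holiday structure, centre
closures correlated with incidence, spatial or opening-hours covariates,
mixed honest/fraudulent behaviour *within* a centre over time, and any
dependence between volume and positivity beyond the category level. Digit
behaviour of honest centres is exactly log-normal, which is cleaner than
reality; the Benford screen's false-positive rate on real honest centres
will be higher than in simulation.

## Numerical conventions and problem sizes

- Flag-count ceilings use `Fraction(str(fraction))` — decimal face value,
  never binary float.
- Reported percentages: exact rationals, half-up to one decimal.
- Laplace inner Newton: convergence when the step's max-norm < 1e-9, with
  step-halving; linear predictors clipped at ±30 before exponentiation.
- Outer Nelder-Mead on log σ with `xatol` 1e-5; σ̂ < 1e-3 is reported as a
  boundary estimate with a warning. Fixing a variance at 0 pins the
  corresponding effects at ~0 via the penalty (floor σ = 1e-6).
- Tie-breaks everywhere: (score descending, centre id ascending).
- Test-suite simulations use 60–160 centres over 15–34 weeks; the
  variance-recovery check uses 300 centres × 50 weeks (≈ 34k model rows,
  fitting in a few seconds); full 907-centre × 73-week screens run in
  ≈ 10 s. These sizes were chosen as the smallest at which the checked
  properties are stable across seeds.

## Known limitations

- The empirical-Bayes z flag rule is a documented stand-in for the pilot's
  unpublished criterion; alternative rules (posterior tail quantiles,
  per-centre likelihood-ratio) would slot into the same interface.
- No overdispersion extension (negative binomial) and no day-level random
  effects; the model is week-level by design.
- The digit screens implement first-digit Benford and last-digit uniformity
  only; second-digit tests, MAD or Kolmogorov–Smirnov statistics are
  extension points.
- Laplace accuracy degrades for centres with very few expected positives;
  the lme4 and quadrature cross-checks cover moderate-information regimes.
- Agreement metrics are point estimates; no confidence intervals or ROC
  analysis are attached.
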