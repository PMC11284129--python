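# Methods

## Oxidative balance score

The OBS sums 20 component scores, each in {0, 1, 2}. Tertile-scored
components use cutpoints at the 1/3 and 2/3 empirical quantiles of the
analytic sample, computed unweighted within each sex stratum, with the
inverted-CDF (order-statistic) quantile convention and right-closed
intervals: `value ≤ t1` falls in the lowest tertile. This convention is
fixed so that an independent sort-and-split recomputation reproduces the
scores bit for bit; on values 1..9 the cutpoints are (3, 6) and the
groups {1–3}, {4–6}, {7–9}. Antioxidant components score `tertile − 1`,
pro-oxidants `3 − tertile`; the identity `antioxidant + pro-oxidant
score = 2` at every value is the polarity-reversal invariant the tests
assert.

Alcohol is the one threshold-scored component. Abstainer means exactly
0 g/day on the dietary recall — the only operational reading of
abstention from intake data. The heavy-drinking boundary is *inclusive*
(intake ≥ 15 g/day for women, ≥ 30 g/day for men scores 0), which makes
the three categories exhaustive and mutually exclusive; intermediate
intakes score 1 and abstention scores 2.

The default component table (16 dietary: fiber, total carotene,
riboflavin, niacin, B6, total folate, B12, C, E, calcium, magnesium,
zinc, copper, selenium as antioxidants; total fat and iron as
pro-oxidants; 4 lifestyle: physical activity as antioxidant; BMI, serum
cotinine and alcohol as pro-oxidants) satisfies the structural
constraints (16/4 split, 5 pro-oxidants, one alcohol-rule lifestyle
pro-oxidant) and is config-overridable: where multiple carotene
variables exist in source data, total carotene is the default and a
YAML table substitutes any other choice; physical activity is tertile-
scored like the nutrients. Missing components are never imputed — rows
with any missing component are excluded upstream (complete-case).

Quartiles of the score use the same quantile convention at the
25/50/75 percentiles, ties falling to the lower quartile. On a discrete
score, tied boundaries can empty a quartile; the model layer then drops
the empty indicator rather than fitting a singular matrix.

## Pooled cohort equations

Coefficients, group mean linear predictors and 10-year baseline
survivals for the four demographic groups live in
`src/oxbal/data/pce_coefficients.yaml` with a provenance string and a
SHA-256 checksum computed at load time, so the transcription is
auditable and replaceable. Survey race categories map black → the
African-American equations and white/other → the white equations (the
guideline's stated practice for groups without their own equations).
Smoking enters as current-smoker status, independent of the cotinine
OBS component. Ages outside [20, 79] are flagged, never clamped —
silent clamping would distort risk — and the exclusion cascade removes
them. The 7.5% threshold is right-closed (risk = 7.5% is high).

## Design-based inference

Point estimates solve the weight-multiplied score equations: logistic
regression by Newton/IRLS, Cox regression by Newton on the weighted
partial likelihood with the Breslow tie convention (simple, documented,
and exact on the continuous event times the generator produces).
Variances are by Taylor linearization: per-row weighted score
contributions (for Cox, weighted score residuals) are summed to PSU
totals; within each stratum the covariance of PSU totals about the
stratum mean, scaled by `n_h/(n_h − 1)`, forms the meat of a sandwich
with the inverse information as bread. A stratum with a single PSU
contributes its deviation from the grand mean of PSU totals and logs a
warning, avoiding silent variance underestimation. With one stratum,
singleton PSUs and equal weights, the standard errors reduce to
heteroskedasticity-robust ones times √(n/(n−1)) — the collapse the
tests verify against an independent maximum-likelihood fit.

Separation in logistic fits is detected (diverging coefficients or a
singular information matrix) and raised explicitly, as is
non-convergence (with the gradient trace) and a zero-event survival
fit. Confidence intervals are normal-theory on the log-odds/log-hazard
scale at a fixed 95% level; odds and hazard ratios are `exp(coef)`
exactly; all p-values are two-sided with 0.05 as the conventional
significance level.

When several survey cycles are concatenated in real data, the analysis
weight should be the cycle weight divided by the number of cycles; the
package consumes whatever weight column it is given, so this division
is the caller's (documented) responsibility. Mortality models are
survey-weighted by default, with the design argument accepting unit
weights for an unweighted sensitivity analysis.

## Restricted cubic splines

The truncated-power natural cubic spline basis with k knots yields k−1
columns (the linear term plus k−2 nonlinear columns), normalised by the
squared knot range for conditioning; value, first and second derivative
are continuous and the function is linear beyond the boundary knots.
Default knots sit at the 5th/35th/65th/95th exposure percentiles — a
standard epidemiological default, configurable in count and location;
on discrete exposures whose quantiles collapse, knots fall back to
evenly spaced distinct observed values. The nonlinearity test is a
joint Wald test of the nonlinear coefficients on the design-based
covariance. Its type-I error at n = 2,000 sits near 5.6% in the
calibration simulations — the mild liberality expected of sandwich-
based Wald tests at this size.

## Quartile trend, interaction, Kaplan–Meier, log-rank

The trend test refits the model with a single ordinal term (1–4)
replacing the quartile indicators; its Wald p is affine-invariant in
the coding. Interaction tests add exposure × modifier products and
Wald-test them jointly. The Kaplan–Meier estimator is the weighted
product-limit; the log-rank test accumulates observed-minus-expected
weighted events with hypergeometric-style variances and reduces to the
textbook test at unit weights.

## Turning-point (two-segment) Cox model

The log-hazard is continuous and piecewise linear in the exposure,
parametrised as `β₁·x + β₂·(x − b)₊`; for each candidate breakpoint b
(every distinct observed exposure value between the 5th and 95th
percentiles, edges excluded) the model is refitted and b is chosen to
maximise the weighted partial likelihood, with the profile returned for
inspection. Left slope = β₁, right slope = β₁ + β₂ (delta-method CI).
A fit whose hinge term fails a 5%-level Wald test is flagged
non-identifiable rather than reported as a discovered break. The CIs
are conditional on the selected breakpoint; post-selection
undercoverage concentrated in replicates where an adjacent grid point
is selected is visible in the recovery simulations and is a known
property of profile-selected breakpoints.

## Synthetic cohort generator

Dietary intakes are sex-shifted log-normals joined by a Gaussian copula
with exchangeable correlation (default ρ = 0.30 on the latent scale,
implying mean pairwise Spearman ≈ 0.29); lifestyle variables use a
weaker ρ = 0.10. Scales were chosen once to give realistic US-adult
intake means (fiber ≈ 17 g/day, calcium ≈ 940 mg/day, …), BMI ≈ 28.6,
physical activity ≈ 2,900 MET-min/week. Cotinine tracks a 17% smoking
prevalence bimodally; alcohol is zero-inflated with 55% abstention on
the recall. Risk factors and model-3 covariates are drawn at realistic
means (TC 206 ± 40, HDL 55 ± 15, SBP 124 ± 18, diabetes 13%, …); the
survey design has 15 strata × 2 PSUs with shifted log-normal weights
drawn independently of the outcome (an ignorable design).

Both outcomes link to the *scored* OBS, not the latent components:
`logit P(high risk) = intercept + β·OBS` (default β = ln 0.94, the
intercept placed so prevalence sits near the one-third high-risk share
typical of US adults) and hazard `λ₀·exp(γ·OBS)` (default γ = ln 0.97,
λ₀ = 0.0037/month, administrative censoring at 192 months plus optional
uniform dropout). This makes the generator's truth exactly the
analysis estimand, so parameter-recovery tests are sharp. Exponential
survival (rather than Weibull) keeps closed-form checks available.

What the generator does *not* emulate: measurement error and day-to-day
variation of 24-hour recalls, item nonresponse patterns, informative
weighting (an optional switch draws weights correlated with nothing by
default), real codebook variable names, and the confounding structure
of a real population — covariates are drawn independently of the OBS,
so adjusted and unadjusted effects coincide in truth. Passing recovery
tests therefore demonstrates correctness of the estimators under the
stated model, not robustness to real-data pathologies.

## Pipeline conventions

Exclusions run in a declared order (missing OBS component → missing or
out-of-range risk-equation input → prevalent ASCVD → missing covariate
→ missing mortality linkage) with first-match attribution, so each row
is counted once and the ledger conserves the total. Tertile cutpoints
are fitted on the post-exclusion analytic sample. The cohort study
restricts to predicted risk ≥ 7.5% before any survival fit. Subgroups
dichotomise age at 60 years and GFR at 60 mL/min/1.73 m²; a modifier
that is itself an adjustment covariate is removed from the covariate
set while it stratifies. The CLI `report` command runs the full
analysis from the input table (fits are not round-trippable through the
JSON results file, so reporting re-runs rather than reloads).

## Problem sizes used in validation

Recovery simulations use 200 replicates at n = 20,000 (logistic,
OR 0.94) and n = 10,000 with ~20% censoring (Cox, HR 0.97); spline
calibration uses 1,000 replicates at n = 2,000 (type I) and 200 for
power; turning-point recovery uses 100 replicates at n = 5,000 with the
exposure drawn bell-shaped over 0–8 as a lifestyle sub-score is. These
sizes give Monte-Carlo standard errors comfortably inside the asserted
tolerances.

## Known limitations

- The Breslow tie convention differs from Efron's on heavily tied
  survival data; the generator produces continuous times where both
  agree.
- Wald/sandwich inference ignores the finite number of PSUs; with very
  few PSUs per stratum a t-reference with design degrees of freedom
  would be preferable.
- The segmented model fits one breakpoint only and its CIs are
  conditional on the selected breakpoint.
- The SAS-transport adapter relies on the host pandas xport reader and
  a user-supplied column map; it performs no codebook validation.
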