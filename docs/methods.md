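# Methods

This note records the models, parameter choices and numerical conventions
behind the package, and what its synthetic-data tests do and do not
demonstrate.

## The four definitions and their boundary conventions

All cut-offs operate on integer UPSIT (0–40) scores. "Below c" is a strict
`< c`; "at or below c" is `<= c`, exactly as the rules are stated.

- **Method 1** (age-corrected): hyposmic if score < 24 at age ≥ 60, < 29
  under 60. Age is age at the olfaction test (the rule is applied at
  testing time).
- **Method 2** (gender-corrected, graded): male bands — < 19 anosmic,
  19–25 severe, 26–29 moderate, 30–33 mild; female — same anosmic/severe
  bands, 26–30 moderate, 31–34 mild. The rule text labels "above 34"
  (male) / "above 35" (female) normosmic, leaving scores of exactly 34 and
  35 unbanded; we assign them normosmic, consistent with the mild caps of
  33 and 34. The binary form is grade ≠ normosmic.
- **Method 3** (age- and gender-corrected): score at or below a smoothed
  normative 15th-centile cut-off looked up by gender and 5-year age band
  (half-open bands `[low, high)`).
- **Method 4**: score at or below a fixed threshold, default 27; an
  empirical within-cohort 15th-centile variant is available
  (`empirical_centile_cutoff`).

An exhaustive boundary audit (41 scores × 2 genders × 5 ages) and
monotonicity/nesting property tests pin these conventions down.

## Scale conversion

Mixed cohorts take either test; rules in UPSIT units reach SS-tested
subjects through a monotone conversion table (every integer 0–40 mapped to
an SS value, non-decreasing, anchored 0→0 and 40→16). The package does not
re-derive the published item-response-theory equating; the table is a CSV
asset, and the shipped default is piecewise linear (0.4 SS per UPSIT point,
rounded to 0.5) for simulation and testing.

Cut-offs, not scores, are converted by default: "at or below c" becomes
`score_ss <= ss(c)` and "below c" becomes `score_ss <= ss(c-1)`, so the
classified set is the image of the UPSIT-scale set. With an injective
table this is exactly equivalent to native classification (verified
exhaustively over all 41 × 41 score/cut-off combinations). The 0.5-rounded
default maps some adjacent UPSIT scores to one SS value; at exactly those
tie boundaries the converted rule is one score more lenient, an
information-loss limit of any many-to-one conversion rather than a
threshold choice. Back-conversion (`to_upsit`) uses the lower preimage:
the minimal UPSIT score whose SS value reaches the target. Score
back-conversion instead of cut-off conversion is available via
`classify_cohort(..., ss_strategy="back_convert_scores")`.

## Normative score model

Published healthy-control norm tables are proprietary to their instruments,
so the counterfactual machinery runs on a configurable parametric stand-in:
per gender, `score = clip(round(intercept_g + slope·(age − 50) + ε), 0, 40)`
with ε ~ N(0, σ). Defaults: women 36.5 UPSIT points at age 50, men 1.5
points lower, slope −0.10 points/year, σ = 4.0 — a slow age decline and a
male disadvantage, the two features the corrected definitions exist to
absorb. These are plumbing defaults, not published values, and every
analysis accepts a different `NormativeModel`.

Because the scores are discretized, exact probabilities are available:
`P(score <= c) = Φ((c + 0.5 − μ)/σ)` for integer c in [0, 40), which the
tests use as a closed-form oracle for simulated means and prevalences.

## Smoothed centile cut-offs

`derive_centile_cutoffs` converts a normative reference sample into
Method-3 cut-offs: per gender and integer age, the threshold within a ±5
year sliding window (widened with a warning under 30 points), then a
local-linear (lowess, frac 0.4) smooth over age, rounding to integer, an
isotonic pass forcing cut-offs non-increasing with age, and emission as
5-year bands.

The windowed threshold is the largest integer whose at-or-below fraction
does not exceed the target centile — the same convention as the empirical
within-cohort cut-off. On a discrete scale with steps of 3–5 percentage
points of mass near the 15th centile, this is the only convention that
keeps the classified fraction at or under the nominal level; taking the
plain empirical quantile instead overshoots to ~16%, and flooring a second
time after smoothing undershoots to ~10.5%. As built, fresh draws from the
same model are classified at ~12.5–13% per gender — under the nominal 15%
by construction, within the band the discreteness permits.

## PD cohort generator

`generate_pd_cohort` draws ages from a truncated normal on (30, 95),
gender as Bernoulli, disease duration as a normal truncated at 0, and a
continuous SS-scale (0–16) score linear in age, male gender and duration
with Gaussian residuals, clipped to [0, 16]. A configurable fraction
(default 0.27) records a Sniffin' Sticks result (rounded to integer); the
rest record the UPSIT score whose conversion is nearest the continuous SS
value (nearest-match rather than lower-preimage, which would bias the
converted scores upward by ~0.25 SS points).

Defaults emulate an early-PD cohort of n = 1674: age 67.8 (SD 9.2), 64.8%
male, duration 1.9 (SD 0.9) years, effect sizes β_age = −0.09/year,
β_male = −0.99, β_duration = −0.20 on the SS scale. The intercept (14.52)
and residual SD (2.84) are solved from the targeted marginal score moments
(mean 7.4, SD 3.0) given those betas and the covariate moments:
14.52 = 7.4 + 0.09·67.8 + 0.99·0.648 + 0.20·1.9 and
2.84² = 3.0² − [(0.09·9.2)² + (0.99·0.478)² + (0.20·0.9)²]. A second
preset (`PPMI_CONFIG`) emulates a younger, all-UPSIT cohort of n = 423
with its own effect sizes.

## Counterfactual simulation

`simulate_counterfactual` keeps each subject's age and gender, redraws one
normative score per subject per replicate, classifies by all four methods,
and reports per method and gender stratum the mean prevalence with the
2.5th/97.5th percentile across replicates as the empirical 95% CI. R
defaults to 2000 (warning below 100); the default seed is 20210630, and
all sampling flows through a single `numpy` Generator, so runs are
bit-reproducible. Resampling per replicate (rather than once) is a
documented choice; the analytic prevalence oracle above confirms the point
estimates converge to the exact expectation.

Under the stand-in normative model, only the corrected-centile method's
control prevalence is pinned near its nominal level by construction
(~13%); the control rates of the fixed-threshold methods depend entirely on
where the stand-in places the healthy score distribution and are not meant
to reproduce any published control percentages.

## Agreement statistics

κ and AC1 are computed from the Q×Q contingency table;
κ uses the product-marginal chance term and the Fleiss–Cohen–Everitt
asymptotic variance, AC1 uses p_e = Σ π_q(1−π_q)/(Q−1) with Gwet's
two-rater linearization variance (a multinomial bootstrap SE is available
as a fallback; the two agree within 20% relative at n = 1000 in tests).
CIs are Wald on the raw scale, clipped to [−1, 1] — chosen for the
symmetric intervals common in applied reports; the bands are the
conventional Landis–Koch labels with inclusive upper edges and "no
agreement" for negatives. `pairwise_agreement` merges the graded method to
binary before tabling (multi-category tables are supported directly).

## Association models

Binary outcomes use maximum-likelihood logistic regression
(statsmodels `Logit`) with the method-specific covariate sets listed in
`regress.py` — each model adjusts only for what its definition does not
already correct. The graded outcome uses a proportional-odds model
(`OrderedModel`, logit link, BFGS). The continuous outcome uses OLS with
residual skewness reported as a diagnostic. Estimates are ORs (logistic
family) or betas (linear) with Wald 95% CIs; age and duration enter
untransformed in years. All models are complete-case on the covariates
used and report the fitted n (the data model allows missing duration).

The Brant test is implemented from its defining construction: fit the J−1
cumulative binary logits `P(Y > c_j)`, stack the slope vectors, build the
joint covariance from `(X'W_j X)^{-1} X'W_jl X (X'W_l X)^{-1}` blocks with
`W_jl = diag(π_l − π_j π_l)` for j ≤ l, and Wald-test equality of slopes
across splits; df = (J−2)·p. Calibration is verified by simulation (type-I
rate within [0.01, 0.10] at α = 0.05 over 200 runs at n = 1000) and a
hand-counted df check (J = 5, p = 2 → 6).

## What the synthetic tests show — and what they do not

The generator reproduces the demographic structure, score moments and
linear effect sizes of a real early-PD cohort, and the qualitative
phenomena of interest emerge from it: wide between-method prevalence
spread, κ ≪ AC1 for the high-prevalence pairs, positive age effects across
outcome scales, and a duration effect detectable on the continuous but not
the dichotomized outcomes. Passing tests therefore demonstrate internal
correctness (formulas, boundaries, convergence to closed-form oracles) and
qualitative fidelity. They do not certify agreement with any real cohort's
exact prevalences or agreement coefficients: real score distributions are
skewed with floor effects and item-level missingness, the true normative
tables differ from the parametric stand-in, and test-version differences
(UK vs US UPSIT) are not modelled.

## Problem sizes and determinism

Default analysis sizes — 100,000-draw normative reference, R = 2000
counterfactual replicates, cohorts of 1674/423, 50-run recovery suites and
200-run Brant calibration — keep every computation to seconds on a single
core while leaving Monte-Carlo error well below the decision thresholds
involved. Every stochastic routine takes an explicit seed or Generator;
report outputs embed the seed and a config hash and are byte-identical
across re-runs of the same configuration.
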