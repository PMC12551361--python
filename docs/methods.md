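# Methods

This note documents the models implemented in `dementia_cohorts`, the
assumptions behind them, the defaults of the synthetic study generator,
and the numerical choices that matter when reproducing results.

## The scientific problem

Age-specific dementia prevalence may differ across birth cohorts: people
born later in the 20th century appear less likely to have dementia at a
given age than their forebears. Measuring that requires (i) imputing
dementia status in large aging panels (HRS-, SHARE-, ELSA-style surveys)
where clinical diagnoses are unavailable, and (ii) separating cohort
effects from age and period effects despite the exact linear identity

    age = calendar year − birth year,

which makes simultaneous linear effects of all three unidentifiable.
The pipeline resolves (i) with an ordered-probit imputation algorithm
calibrated against a clinically adjudicated subsample and (ii) by coding
age and cohort as dummy blocks while substituting a *measured* period
variable — the annual GDP growth rate of the respondent's own country —
for calendar-year effects.

## Age groups and birth cohorts

Respondents enter the analysis only at interviews where their exact
calendar-year age (interview year − birth year, no birth-month
adjustment) is at least 71. Six age groups are used: 71–75, 76–80,
81–85, 86–90, 91–95, ≥96. Cohort bins are closed intervals specific to
each survey dialect: the US panel has 8 bins (a wide 1890–1913 reference
followed by 1914–1918 and 5-year bins up to 1944–1948); the European and
English panels have 7 bins with reference cohorts 1901–1918 and
1908–1918 respectively. Both binnings tile their year ranges with no
gaps, and the first bin is always the regression reference. New surveys
can be described by a YAML dialect file without code changes.

## Dementia imputation

**Model.** For each respondent kind (self-interview vs proxy interview)
a separate ordered probit is fitted to the 3-class clinical status
(normal / cognitively impaired not demented / dementia). The latent
variable is an impairment index `z = xβ + ε`, `ε ~ N(0,1)`; cutpoints
κ1 < κ2 give `P(normal) = Φ(κ1 − xβ)` and `P(dementia) = 1 − Φ(κ2 − xβ)`.
The orientation is fixed so a *larger* fitted index always means a
*higher* dementia probability; this removes a sign ambiguity that
ordered-category conventions otherwise leave open.

**Features.** Demographics (age, gender, education), ADL/IADL limitation
counts, current cognitive scores (word recall 0–20, serial sevens 0–5,
orientation 0–4 for self-respondents; an informant questionnaire score
1–5 for proxies), and the change of each score relative to the same
person's previous wave of the same kind. Change features are zero at the
first observed wave, with a companion first-wave indicator. Missing
features are mean-imputed within kind with a companion missing
indicator. The feature list is configuration, not hard-coded: surveys
lacking an instrument simply omit it.

**Fitting.** Maximum likelihood via BFGS on the mean log-likelihood with
an analytic gradient. The cutpoint gap is reparameterized as
κ2 = κ1 + exp(g), so κ1 < κ2 holds unconstrained; three starts (the
closed-form intercept-only solution plus two jittered copies) guard
against local optima. Rank-deficient feature matrices and diverging
coefficients (perfect separation) raise errors naming the offending
columns. For small quasi-separated calibration samples the pipeline
retries once with a weak L2 penalty (ridge = 0.01) on the slopes and
logs the fallback; reported log-likelihoods are always unpenalized.
When only the two extreme classes are present the same code path
reduces exactly to a binary probit.

**Classification and validity.** The default decision rule tunes a
threshold on the predicted dementia probability over a 0.005-step grid,
maximizing binary accuracy on the gold-standard *calibration* half
(ties → lower threshold); `argmax` over the three class probabilities is
available as an alternative. Validity — percent agreement between
imputed and clinical dementia status — is always reported on the
held-out *validation* half, split 50/50 by person, so it is out of
sample by construction.

**MLP robustness backend.** A single-hidden-layer perceptron (default
32 ReLU units, softmax output, cross-entropy loss) trained by plain
mini-batch SGD at a fixed learning rate (0.03, batch 32) with early
stopping: training halts when validation performance (20% of the
training split) has not improved for 30 consecutive epochs, restoring
the best epoch's weights. The patience and validation fraction are
deliberately generous because calibration samples are a few hundred
cases — with short patience the network stops before learning the proxy
model. Validity is defined identically, so the two backends are
directly comparable.

## The age-period-cohort model

The binary imputed outcome is modelled per person-wave as

    P(dementia_it = 1 | u_i) = F(x_it'β + u_i),    u_i ~ N(0, σ_u²),

with F the probit (default) or logistic link. `x_it` contains an
intercept, age-group dummies (reference 71–75), cohort dummies
(reference: the dialect's first cohort), and the period block — either
survey-year dummies (reference: first year) or the single GDP growth
value of the respondent's own country in the interview year (pooled
multi-country fits never use a cross-country average). The probit link
is the default because its coefficient scale matches both the upstream
ordered probit and the latent-normal generator; with the generator's
occasion noise fixed at SD 1, true effects are recovered on their
original scale.

**Estimation.** The person-level marginal likelihood integrates the
random intercept by adaptive Gauss–Hermite quadrature: per person, a
damped Newton search finds the posterior mode of u, the local curvature
rescales the (default 9, configurable) Hermite nodes, and the integral
is accumulated in log space. The score is evaluated holding the adapted
nodes fixed — the mode is a stationary point, so the neglected
correction is higher order — and optimization is L-BFGS-B over (β,
log σ_u) with log σ_u bounded in [−9, 3]; a fit at the lower bound is
reported as σ_u = 0. Nine nodes are already quadrature-converged for
panels of ≤6 waves (doubling the nodes moves estimates by < 0.002), and
against `lme4::glmer(nAGQ = 15)` the implementation agrees to ~1e-5 on
a shared fixture. `re="none"` gives ordinary ML probit/logit by Fisher
scoring instead.

**Uncertainty.** Because the marginal likelihood factorizes over
persons, per-person score contributions give the clustered sandwich
directly: `cov = H⁻¹ (Σ_i g_i g_i') H⁻¹` with H the observed information
(finite differences of the analytic score). Reported 95% CIs are
estimate ± 1.96 × cluster-robust SE with two-sided normal p-values;
model-based SEs are retained alongside. With one observation per
cluster the clustered sandwich reduces exactly to the
heteroskedasticity-robust (HC0) covariance. The model already contains
a person random intercept; the clustered CIs are kept on top of it as
the reporting convention for repeated measures, and both SE flavours
are exported so their difference is visible.

**Identifiability diagnostics.** `check_identifiability` runs a
singular-value analysis of the column-normalized design; rank
deficiency (σ_min/σ_max < 1e-8) is reported with each null direction
expressed as a combination of the original columns, scaled to largest
coefficient 1. The deliberately degenerate continuous
age + year + birth-year design yields the null vector ∝ (1, −1, 1) —
the APC identity itself. Dummy-coded designs with a GDP period proxy
are full rank. `fit_glmm` refuses rank-deficient designs rather than
silently dropping columns.

## The synthetic study generator

The generator exists because the real survey micro-data are restricted
access; it emulates their structure closely enough that every stage of
the pipeline can be tested by parameter recovery.

Latent cognition of person i at wave t is

    c_it = age_effect(group_it) + cohort_effect(cohort_i)
           + λ · gdp_growth(country_i, t) + u_i + ε_it,

with u_i ~ N(0, σ_ind²), ε_it ~ N(0, σ_noise²), lower = worse. Clinical
truth is deterministic given the draw: dementia below κ1, impaired
between κ1 and κ2, normal above κ2 — standing in for an expert-consensus
adjudication. Because dementia = 1{c < κ1} and σ_noise = 1, a cohort
shift of +δ on the cognition scale is exactly −δ on the dementia probit
scale, which is what the APC model estimates.

Defaults (one synthetic study ≈ one survey's analysis sample):

| parameter | default | rationale |
|---|---|---|
| persons / waves | 10 000 / six biennial (2004–2014) | large-panel regime at desk scale |
| birth years | 1909–1943, uniform | spans 7 US-dialect cohort bins at ages 71+ |
| age effects | 0 → −1.6 across the six groups | prevalence rising from ~3% to ~45% with age |
| cohort effects | 0 → +0.55 (improving) | probit-scale gradient of the size large panels report |
| period coupling λ | 0.03 per growth point | small pro-cyclical health effect |
| σ_ind / σ_noise | 0.5 / 1.0 | persistent individual differences ≈ ¼ of latent variance |
| cutpoints (κ1, κ2) | (−1.7, −0.8) | ~19% dementia, ~20% CIND overall among 71+ |
| proxy model | logit(p) = −(3.0 + 1.5·c) | ~20% proxy waves, concentrated among the impaired |
| attrition | 10% per wave, cognition-independent | biennial panel loss; an optional slope links exit to impairment |
| gold fraction | 10% of persons, one wave each | a one-time clinical substudy |

Observables are noisy truncated-affine views of the latent scale (score
= round(clip(a + b·c + noise))), ADL/IADL counts are Binomial(5, ·) with
rates rising as cognition falls, and proxy waves replace self-test
scores with an informant score. All randomness derives from one root
seed through named substreams, so stages are individually reproducible
and two panels differing only in, say, the GDP draw are otherwise
identical.

**What the generator does not emulate:** survey weights, household
structure, country heterogeneity beyond the GDP value, item-level
missingness patterns, practice effects on repeated testing, or
mortality as distinct from generic attrition. Passing recovery tests
therefore show the *estimators* are correct under the assumed
data-generating process, not that the substantive published estimates
are reproduced — those require the restricted micro-data.

## Monte-Carlo evaluation scales

The recovery studies use a 4-cohort design (birth years 1914–1933,
true dementia-scale cohort effects 0, −0.2, −0.3, −0.5) with GDP-driven
period effects (AR(1) growth, innovation SD 2): sign-and-ordering
recovery over 100 replicates at 10 000 persons; CI coverage pooled over
the three cohort coefficients across 200 replicates at 2 000 persons;
year-mode vs GDP-mode sign concordance over 20 replicates at 4 000
persons. `scripts/acceptance.py` runs the same studies at smaller
replicate counts (20 / 60 / 10) chosen to keep a full from-scratch run
to a few minutes; the test suite runs the full sizes.

## Known limitations

- The fixed-node AGQ score is an approximation to the exact derivative
  of the quadrature objective; with ≥9 nodes the discrepancy is far
  below statistical noise, but pathological clusters could in principle
  slow convergence (reported honestly via `converged`).
- Mean-imputation with indicators is a pragmatic missing-data choice;
  the surveys' own practice of dropping items unavailable in some waves
  is supported at the feature-configuration level instead.
- The cutoff rule maximizes overall accuracy, which under strong class
  imbalance can favour specificity over sensitivity; the calibrated
  cutoff is logged so this is auditable.
- Attrition in the generator is independent of cognition by default;
  the optional cognition-linked hazard exists precisely to study the
  resulting underestimation of prevalence, but no correction is
  implemented.
- σ_u is estimated on the log scale with a floor; data truly at σ_u = 0
  sit on the boundary and small positive estimates at modest n are
  expected sampling behaviour.
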