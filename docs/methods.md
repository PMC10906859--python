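# Methods

## The model

Mental health status is operationalised with the dual-factor model: two
correlated but distinct continua — mental well-being, measured by the
MHC-SF, and mental health problems, measured by the SDQ — are each
dichotomised and crossed into four groups (Complete, Symptomatic but
content, Vulnerable, Troubled).  The pipeline scores the instruments,
classifies respondents, compares the groups, and models group membership
against the Complete reference with binary logistic regressions.  No
multinomial pooling is attempted: each contrast is a separate binary
model, which is what the pairwise odds ratios describe.

## Scoring conventions

**MHC-SF.**  Items 1–3 are the emotional well-being items, items 4–14 the
positive-functioning (social + psychological) items; a codebook maps
arbitrary input columns onto this order.  *Flourishing* requires a rating
of 4–5 ("almost every day"/"every day") on ≥1 emotional item and ≥6 of
the 11 functioning items; *languishing* the same counts with ratings 0–1;
the two criteria are mutually exclusive by arithmetic (6+6 > 11, checked
by a property test).  The total (0–70) requires all 14 answers.  For the
categorical diagnosis, the default policy counts bands over answered
items only, so unanswered items qualify for neither band and incomplete
responders drift toward *moderate* (hence the collapsed moderate-to-low
band); this keeps respondents with a stray missing item classifiable,
which a dual-factor tabulation of a whole cohort needs.  A strict
complete-case mode (`strict=True` / `AnalysisConfig.mhc_strict`) is
available.

**SDQ.**  Standard published self-report scoring: subscales
emotional {3, 8, 13, 16, 24}, conduct {5, 7R, 12, 18, 22}, hyperactivity
{2, 10, 15, 21R, 25R}, peer {6, 11R, 14R, 19, 23}, prosocial
{1, 4, 9, 17, 20}; the five positively-worded difficulty items (R) are
inverted (2 − raw) before summing.  Total difficulties sums the four
problem subscales (0–40); caseness is total ≥ 20 (90th percentile of a UK
norm sample; configurable via `AnalysisConfig.sdq_caseness_cutoff`).
Missing policy is complete-case per subscale by default; the standard
prorating rule (scale mean × 5, half-up, when ≥3 of 5 items answered) is
available behind a flag.

**CYRM-12** sums 12 items (1–5) to 12–60, missing if any item is missing.

**Cronbach's α** uses the classical formula k/(k−1)·(1 − Σs²ᵢ/s²ₜ) with
sample variances over complete-case rows; α can be negative for
pathological data and an error is raised when the total variance is zero.

## Exclusion cascade

Three sequential filters, in the order the counts are reported:
(1) height or weight beyond mean ± 2 SD, with mean and sample SD (ddof 1)
computed on the full input set — the screen against unreliable
responding; (2) other/unsure gender identity; (3) listwise deletion on
the required variables (gender, birth country, both guardian occupations,
grade, grade-F, truancy, stress, all CYRM and SDQ items — MHC items and
the SSS ladder are deliberately not required, since incomplete responders
on those are retained and handled downstream).  Each excluded record is
logged once under the first rule that fired, and the audit reconciles
n_input − (24+59+292-style counts) = n_final exactly.  Because filter (1)
fixes its bounds on the input set, re-running the cascade on its own
output recomputes them on the reduced set and is not guaranteed
idempotent; filters (2) and (3) are.

## Group statistics

Categorical variables: Pearson χ² without continuity correction on the
groups × levels table, switching to Fisher's exact test when any expected
cell count is below 5 (threshold configurable).  The 2×2 Fisher p-value
is the usual two-sided hypergeometric sum; r×c tables use full
enumeration of tables with the observed margins (probability ordering) up
to total 400, and Patefield Monte-Carlo sampling with a fixed internal
seed beyond that.  Pairwise column-proportion comparisons are
two-proportion z-tests with Bonferroni adjustment within the variable —
the convention of mainstream survey software — each pair also reporting
Cohen's h.

Continuous variables: one-way ANOVA with Tukey–Kramer adjusted pairwise
p-values (unequal n handled), each pair also reporting Cohen's d.
Normality is assessed descriptively via bias-adjusted (G1/G2) skewness
and excess kurtosis.

**Effect-size conventions.**  Cohen's h = |2·arcsin√p₁ − 2·arcsin√p₂|.
Cohen's d uses the equal-weight RMS denominator √((s₁²+s₂²)/2) — not the
n-weighted pooled SD.  With group moments such as 48.9 (5.6) vs 40.0
(7.1) the RMS denominator gives 1.39 where n-weighted pooling gives 1.47;
the RMS form is the one consistent with the reported contrasts this
pipeline mirrors, and it is the package default.  Effect sizes are
reported as magnitudes; direction is recoverable from the group
statistics.

## Logistic modelling

Maximum-likelihood binary logistic regression (complete-case on outcome
and design), Wald standard errors, OR = exp(β) with CI95 =
exp(β ± 1.96·SE).  On a saturated single-binary-predictor design this
reproduces the closed-form cross-product OR and the Woolf interval to
1e-6, which is tested.  Reference levels: boy, Sweden, no guardian flag,
lower secondary, no F grade, never truant, low stress; CYRM and SSS enter
untransformed per point.  Perfect or quasi-separation is detected from
diverging standardised coefficients or exploding Wald SEs and raised as
an error rather than reported.  The multivariable model contrasts
Vulnerable vs Complete only (the other groups are too small for adjusted
modelling) and is complete-case on SSS, mirroring the protocol.

Diagnostics: Nagelkerke R² = R²_CS / (1 − exp(2·L₀/n)) with
R²_CS = 1 − exp(2(L₀−L₁)/n); Hosmer–Lemeshow over g = 10 groups formed by
quantiles of the fitted probabilities with ties never split across bins,
χ² summed over both outcome classes, df = g − 2 (note: with heavy ties
fewer than g distinct bins can form, and df shrinks accordingly);
VIF_j = 1/(1−R²_j) from an OLS regression of each predictor on the others
plus intercept, flagged at max ≥ 10.  The Bonferroni threshold is
α/m where m defaults to the number of tests the run actually performed
(the default full analysis performs 9 omnibus + 27 univariate + 1
multivariable = 37 tests, so the displayed threshold is 0.0014); m can be
pinned in the config.

## Synthetic cohort generator

Each respondent carries a bivariate-normal latent pair (W, P) — 
well-being and problems — with correlation `latent_correlation`
(default −0.55).  Girls receive configurable shifts (defaults −0.35 on W,
+0.70 on P), and covariate levels (stress, grade-F, truancy) add further
shifts; covariates are drawn independently given gender from marginals
resembling a Swedish grade 7–12 cohort.  Items follow a graded-response
mechanism: item latent = trait + N(0, 0.8), discretised through fixed
per-instrument thresholds; CYRM and SSS load on W with loadings 0.6 and
0.5.  Missingness is MCAR on SSS (10.9%), MHC items (11.3%, 1–3 items)
and the required variables (13.2%), and height/weight are age-dependent
truncated normals with a configurable rate (1.1%) of injected ±(2.5–4) SD
outliers.  One integer seed drives a single root generator, so identical
configs give byte-identical cohorts.

The item thresholds, gender effects and stress effects are calibration
constants, set once by pilot simulation so the default cohort lands near
a realistic adolescent survey: ~37% flourishing, ~17% SDQ caseness, ~42%
reporting considerable stress, CYRM mean ≈ 45, SSS mean ≈ 6.5, and an
observed MHC–SDQ Spearman ρ ≈ −0.56 (the −0.55 latent correlation is
likewise a calibration constant, not an estimate).  On the latent scale
the Gaussian-copula identity ρ_S = 6/π·arcsin(ρ/2) holds; discretisation
and item noise attenuate the observed rank correlation slightly, which
the tests bound rather than ignore.

What the generator does **not** emulate: covariate–covariate dependence
beyond gender (real stress and truancy co-occur); informative
missingness; measurement non-invariance across groups; and realistic
item-level heterogeneity — with a single shared noise SD per instrument
the synthetic internal consistencies (α ≈ 0.95) are higher than typical
real questionnaire data (0.7–0.9).  Passing tests therefore demonstrate
the correctness of scoring, classification and inference machinery under
a known data-generating process, not distributional fidelity of any real
cohort.  Height/weight residuals are truncated at 1.3 conditional SD so
the marginal 2-SD screen flags essentially only the injected outliers;
real anthropometric tails are heavier.

## Numerical choices and degenerate inputs

Percentages are rounded half-up to 1 dp for report parity (internals stay
full precision); ORs and effect sizes display at 2 dp; p-values at 3 dp
with a "<0.001" floor.  Summary percentiles use type-7 (linear
interpolation) quantiles.  Constant samples raise errors from moments,
Spearman and Cronbach's α rather than returning silent zeros; zero cells
make the closed-form OR an error unless the Haldane–Anscombe +0.5
correction is requested explicitly; degenerate contingency margins and
empty cohorts are errors naming the condition.

## Problem sizes

The shipped test-suite and acceptance runs use cohorts of 300–10,000
respondents (2,208 for the pipeline examples, 10,000 for copula
calibration checks, 10 × 5,000 for parameter recovery, 500 × 300 for CI
coverage), sizes at which the binomial/Monte-Carlo tolerances asserted in
the tests were pre-registered from the pilot simulation.

## Known limitations

The exact wording-level codebook of the original Swedish questionnaire is
abstracted away; the package operates on category codes.  The Fisher
Monte-Carlo path yields simulation p-values (deterministic via a fixed
seed) rather than exact ones for large sparse tables.  Adjusted
(multivariable) odds ratios are structurally reproduced on synthetic data
only — they depend on raw survey data this package does not ship.  No
imputation is offered; all missing-data handling is listwise or
band-tolerant as described above.
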