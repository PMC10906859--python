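# dualfactor

Dual-factor mental-health analysis of adolescent school-survey data, as a
reusable, tested Python pipeline.

The dual-factor model treats mental **well-being** and mental **health
problems** as two distinct, negatively correlated continua rather than two
ends of one scale.  Crossing a categorical well-being band from the Mental
Health Continuum — Short Form (MHC-SF) with caseness on the Strengths and
Difficulties Questionnaire (SDQ) assigns every respondent to one of four
status groups:

|                      | no problems (SDQ < 20) | problems (SDQ ≥ 20)          |
|----------------------|------------------------|------------------------------|
| **flourishing**      | Complete (C)           | Symptomatic but content (S)  |
| **moderate-to-low**  | Vulnerable (V)         | Troubled (T)                 |

The package covers the full analysis protocol of a survey of this design:

* **Instrument scoring** — MHC-SF (14 items, 0–5): total 0–70 and the
  categorical diagnosis (*flourishing* = rating 4–5 on ≥1 of 3 emotional
  items **and** ≥6 of 11 functioning items; *languishing* analogously with
  ratings 0–1); SDQ self-report (25 items, 0–2): five subscales with the
  standard reverse-scored items, total difficulties 0–40, caseness at
  ≥ 20; CYRM-12 resilience (12–60); Cronbach's α for any item matrix.
* **Cohort handling** — codebook-driven CSV ingestion, Table-style
  covariate dichotomisation (stress, truancy, grade F, guardian
  occupation, birth country, school level), and a three-step exclusion
  cascade (height/weight beyond mean ± 2 SD → other/unsure gender →
  listwise missing-required) with a reconciled audit.
* **Group statistics** — χ² / Fisher-exact omnibus tests, one-way ANOVA
  with Tukey–Kramer post-hocs, Cohen's *h* = |2·arcsin√p₁ − 2·arcsin√p₂|
  and Cohen's *d* = |m₁ − m₂| / √((s₁² + s₂²)/2), tie-aware Spearman ρ,
  bias-adjusted skewness/kurtosis.
* **Inference** — binary logistic regressions of each group against the
  Complete reference (OR, Woolf/Wald 95% CI, p), Nagelkerke R², the
  Hosmer–Lemeshow calibration test over deciles of fitted risk, a VIF
  collinearity screen, and a Bonferroni-corrected significance threshold.
* **Synthetic cohorts** — a Gaussian-copula generator (correlated latent
  well-being/problems traits, graded-response items, configurable
  covariate effects, MCAR missingness, injected height/weight outliers)
  so the entire pipeline runs and is validated without any external data.

## Worked example

```python
from dualfactor import DualFactorModel, SimConfig, generate_cohort

cohort = generate_cohort(SimConfig(n_respondents=2208, seed=1))
results = DualFactorModel(cohort).fit()
print(results.summary())
```

```
Dual-factor mental-health analysis
==================================
input records            2208
  height/weight outliers 40
  other/unsure gender    50
  missing required       290
retained                 1828

Status groups (of classified respondents):
  C complete                 n =   643  (35.2%)
  S symptomatic_but_content  n =    25  (1.4%)
  V vulnerable               n =   883  (48.3%)
  T troubled                 n =   277  (15.2%)

MHC-SF vs SDQ Spearman rho: -0.57
Bonferroni threshold: 0.0014 (alpha=0.05, m=37)
Adjusted model (V vs C): n=1366, Nagelkerke R2=0.35
  Hosmer-Lemeshow chi2=17.18 (8) p=0.028
VIF range 1.00-1.13
```

Reading the output: of 2,208 simulated respondents, 1,828 survive the
exclusion cascade; about half are *Vulnerable* (moderate-to-low well-being
without SDQ caseness) — the group a problems-only assessment would miss.
The two instruments' totals correlate negatively (ρ ≈ −0.57), the adjusted
Vulnerable-vs-Complete model explains a moderate share of variation
(Nagelkerke R² 0.35), and the VIF range shows the predictors are not
collinear.  The analysis runs 37 tests, so the Bonferroni-corrected
significance threshold is 0.05/37 ≈ 0.0014.

`results.tables()` returns the report tables (descriptives, instrument
summary, status cross-table, group comparisons with effect sizes,
unadjusted ORs per group, adjusted model), and `results.save("out/")`
writes them as TSV plus a reproducibility manifest.  The same pipeline is
available from the shell:

```sh
dualfactor simulate --out cohort.csv --seed 1 --n 2208
dualfactor report --in cohort.csv --out-dir results/
```

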