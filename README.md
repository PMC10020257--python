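# brisk-model

A toolkit for simple multiplicative breast-cancer risk prediction and for
validating risk prediction models on nested case-control data.

Most women never see a pedigree clinic: risk assessment has to work from a
handful of factors a mammography practice can actually collect. This package
implements that style of model — the combined relative risk of a woman is
the product of independently acting, population-centered components

```
RR = RR_family-history x RR_density x RR_BMI|menopause x PRS
```

where each categorical component is *centered* (raw category risks divided
by their prevalence-weighted mean, so the population average is 1),
continuous components are log-linear around a reference value, and the
polygenic risk score (PRS) is the Mealiffe-style product over SNPs

```
PRS = prod_k  r_k^g_k / mu_k,    mu_k = (1-p_k)^2 + 2 p_k (1-p_k) r_k + p_k^2 r_k^2
```

normalized by the Hardy-Weinberg mean `mu_k` so that E[PRS] = 1. Because
every component averages to 1, `RR` multiplies the population baseline
hazard directly, and absolute risk over a horizon is the competing-risk
cumulative incidence with piecewise-constant annual hazards h1 (incidence)
and h2 (other-cause mortality):

```
P(a, tau) = sum_{t=a}^{a+tau-1}  rr*h1(t)/(rr*h1(t)+h2(t)) * (1 - e^{-(rr*h1(t)+h2(t))}) * S(a, t)
```

with `S` the all-cause survival from `a` to `t` — exact for the declared
hazard model.

The validation half implements the statistics used to compare such models
in case-control studies: odds ratio per control-SD of score, AUC with the
DeLong variance and the DeLong test for correlated AUCs, median-based
expected/observed calibration with a log-scale CI, clinical risk-category
reclassification tables, and the categorical net reclassification
improvement (NRI) with Pencina-Steyerberg standard errors. A synthetic
cohort generator (controls from the population model, cases sampled with
probability proportional to their true relative risk) makes the whole
pipeline testable without access-controlled cohort data, and the package
ships the published count tables of a 1131-case / 1700-control validation
study as self-checking fixtures.

## Worked example

```python
from brisk import (RiskFactorProfile, default_parameters, default_hazards,
                   absolute_risk, remaining_lifetime_risk)
from brisk.risk_engine import profile_rr

params = default_parameters()      # documented approximate tables
hazards = default_hazards()        # synthetic baseline rates

woman = RiskFactorProfile(age=52, n_fdr=1, age_youngest_fdr=44,
                          percent_density=38.0, bmi=27.5,
                          menopausal_status="post", prs=1.8)
rr = profile_rr(woman, params)
print(round(rr, 3))                                       # 4.748
print(round(absolute_risk(woman.age, 5, rr, hazards), 4)) # 0.0603
print(round(remaining_lifetime_risk(woman.age, rr, hazards, 85), 4))  # 0.3799
```

One affected first-degree relative diagnosed young, dense breasts,
postmenopausal overweight and a PRS of 1.8 multiply to a combined relative
risk of 4.7; against a baseline 5-year risk of 1.3% at age 52 this projects
to a 6.0% 5-year risk and a 38% remaining-lifetime risk to age 85 — both
far above the 1.67%/3% chemoprevention and 20%/25% screening thresholds.
The shipped parameter tables and hazard rates are deliberately round,
clearly labelled approximations; calibrated tables drop in via a YAML
config and a hazard CSV.

The same pipeline from the shell:

```
brisk simulate --n-cases 150 --n-controls 300 --seed 42 --out cohort.csv
brisk score    --cohort cohort.csv --out scored.csv
brisk validate --scored scored.csv --old brisk5 --new brisklt \
               --scheme five_year --out report/
brisk fixtures table4
```

The last command recomputes a published reclassification table's summary
statistics from its raw counts:

```
table4
  NRI recomputed: overall 0.312 (0.031), cases 0.415 (0.023), controls -0.103 (0.021)
  printed: overall 0.310 (0.031), cases 0.415 (0.023), controls -0.103 (0.021)
  cases at/above 1.67% under new model: 72.2%
  cases at/above 3% under new model: 51.0%
```

## Layout

- `brisk.risk_engine` — profiles, parameter tables, hazards, the combined
  relative risk and the competing-risk projection
- `brisk.prs` — HWE-normalized polygenic score; SNP weight TSV, VCF and
  dosage-matrix input
- `brisk.validation` — OR/SD, AUC/DeLong, calibration, reclassification, NRI
- `brisk.synthetic` — case-control cohort simulator
- `brisk.fixtures` — packaged published tables with marginal self-validation
- `brisk.io`, `brisk.report`, `brisk.cli` — file formats, report assembly,
  command-line surface

See `docs/methods.md` for the model's assumptions, parameter conventions
and known limitations.
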