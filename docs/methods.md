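# Methods

## The risk model

The model treats breast-cancer risk factors as acting multiplicatively and
largely independently. Each woman's combined relative risk is

RR = RR_fh · RR_dens · RR_bmi · PRS,

with the conventions:

- **Family history** is a banded table over (number of affected
  first-degree relatives, age at diagnosis of the youngest, number of
  affected second-degree relatives). Each band carries a raw relative risk
  and a population prevalence weight; the returned value is the raw RR
  divided by the prevalence-weighted mean, so the population average of the
  component is exactly 1. Band matching is first-match over ordered,
  inclusive ranges; a profile no band covers is a configuration error, not
  a silent 1.
- **Mammographic density** runs in one of two modes: continuous
  (`exp(slope · (percent − reference))`, slope in log-RR per percent) or
  categorical (centered band RRs with prevalence weights, bands delimited
  by percent-density edges so either a Cumulus-style reading or a
  radiologist category can be supplied).
- **BMI** is log-linear per kg/m² with separate slopes by menopausal
  stratum — the association reverses direction between pre- and
  post-menopause, so a single slope would be wrong in both strata.
- **PRS** is the product over SNPs of `r^g / μ(p, r)` with
  `μ = (1−p)² + 2p(1−p)r + p²r²`, the Hardy–Weinberg population mean of
  `r^g`. Under HWE with independent loci E[PRS] = 1, making the score a
  centered component like the others. Missing genotypes contribute the
  factor 1 (the population mean), keeping scores centered and the sample
  size constant. Scores are carried on the natural mean-1 scale; logs are
  taken only inside validation statistics.

Because every component is centered to population mean 1, the combined RR
multiplies the baseline incidence directly; no attributable-risk deflation
of the hazard is applied.

## Absolute risk under competing mortality

Hazards are piecewise-constant on one-year age intervals: h1(t) is
breast-cancer incidence, h2(t) other-cause mortality, both per woman-year.
The cause-specific cumulative incidence has the exact per-year closed form
given in the README; the year-level sum is therefore exact for the declared
hazard model, with no step-size parameter. The cause fraction
`rr·h1/(rr·h1+h2)` is defined as 0 where both rates vanish. Real-valued
ages are floored to index hazard years. Tests verify the interval-splitting
identity P(a, τ1+τ2) = P(a, τ1) + S(a, τ1)·P(a+τ1, τ2) to 1e-12, the
closed form 1 − exp(−Σh1) when h2 = 0, and agreement with an independent
day-step numerical integration to 1e-4.

Remaining lifetime risk integrates to a horizon age of **85** by default
(configurable): the natural lifetime endpoint is not standardized across
guidelines, and 85 mirrors common US practice. Five-year risks at ages
above horizon−5 require hazard coverage; the shipped table covers ages
20–89.

## Default parameter tables

The shipped defaults are **documented approximations**, not calibrated
values: family-history raw RRs (none 1.0 / SDR-only 1.3 / one FDR 1.7 or
2.3 by diagnosis age under 50 / two-plus FDR 2.9, prevalences
65/20/8/5/2%) follow the familiar pattern of the large collaborative
reanalyses; density slope 0.02 per percent around 25%; BMI slopes +0.03
(post) and −0.02 (pre) per kg/m² around 25. The baseline hazard table is a
synthetic interpolation of the familiar age-incidence curve (rising to
~4/1000 woman-years in the 70s) with Gompertz competing mortality. All of
these are external configuration (YAML parameter file, hazard CSV) so that
calibrated tables can be dropped in without touching code; results obtained
with the defaults demonstrate machinery, not clinical calibration.

No cap is applied to the combined RR by default; an optional `rr_cap`
truncates and is logged when it fires.

## Validation statistics

- **OR per SD**: univariable logistic regression of case status on
  score/SD, where SD is the control-arm standard deviation (denominator
  n−1) — controls approximate the population spread. CIs are Wald; the
  profile-likelihood alternative differs negligibly at validation sample
  sizes.
- **AUC**: Mann–Whitney with midrank tie handling; variance and CI from
  the DeLong placement-value estimator.
- **DeLong comparison**: placement values V10 (per case) and V01 (per
  control) per model; the variance of ΔAUC combines the 2×2 covariance
  matrices of the paired placements; (ΔAUC)²/var is χ²(1). Zero variance
  with nonzero ΔAUC reports an infinite statistic with a warning; with zero
  ΔAUC the statistic is 0 and p = 1.
- **Categorization**: clinical schemes (5-year: 1%, 1.67%, 3%; lifetime:
  6%, 12%, 20%, 25%) with left-closed, right-open intervals — a risk
  exactly on an edge belongs to the upper category, matching how the
  thresholds are applied clinically ("at or above").
- **NRI**: from the K×K case and control cross-classification counts,
  net(arm) = (up − down)/n with controls credited for moving down; the
  per-arm standard error is the Pencina–Steyerberg
  `sqrt((p_up + p_down − (p_up − p_down)²)/n)` and the overall SE the
  root-sum-square of the two arms. Integer arithmetic until the final
  divisions.
- **Calibration**: on controls (representative of the population), per age
  band (<45, 5-year bands, 75+): expected = median score × N,
  observed = population risk × N; the **median** is used because risk-score
  distributions are strongly right-skewed. The E/O interval is
  `(E/O)·exp(∓1.96/√E)` — a Poisson-type log-scale interval on the expected
  count, adopted because it exactly reproduces the reference tables'
  printed intervals; it treats E as the stochastic count.
- Subjects missing one model's score are dropped pairwise for that
  comparison only, mirroring validation studies where a comparator is
  available on a subset.

## Synthetic cohorts

The generator emulates a nested case-control design: controls are drawn
from the population covariate model; cases are drawn from a population pool
of 50× the requested number with probability proportional to their
combined RR (weighted sampling without replacement via exponential races),
which is the correct retrospective sampling law for a rare outcome.
Covariate families: truncated-normal age (59.3 ± 7.5, 40–78) and BMI
(25.9 ± 4.7), logit-normal percent density moment-matched to mean 24.7 /
SD 18.1 (the logit-normal respects the [0,100] support; only mean and SD
of the real data are published, so the family is a modelling choice),
family-history categories drawn at the parameter table's own prevalence
weights, menopausal status logistic in age around 50, and a PRS that is
either computed from HWE genotypes at supplied SNP weights (independent
loci, no LD) or drawn log-normal with configurable log-SD (default
ln 1.61, the published discrimination of the 313-SNP score) and arithmetic
mean 1.

What the generator does **not** emulate: covariance among risk factors
beyond what the RR model induces, secular/age trends in density beyond the
marginal, LD between loci, measurement error in density or BMI, and
real-world miscalibration. Passing recovery tests therefore show that the
pipeline is statistically faithful to its own model — not that the model is
calibrated to any particular population. Case-control covariate differences
arise solely through RR-weighted case sampling; in real nested designs
matching and sampling artifacts contribute too. Determinism: a (spec, seed)
pair reproduces the cohort byte-identically.

## Packaged reference tables

The fixture JSONs transcribe the published count tables of a
1131-case/1700-control model-validation study (881/1327 for the
lifetime-risk comparator subset). Every file embeds row, column and grand
totals and the loader re-derives them from the raw cells, failing loudly on
any mismatch; calibration columns must sum to their printed totals within
0.05 (accumulated two-decimal rounding). One table's published summary
improvements disagree slightly with recomputation from its own printed
counts (0.381/−0.094 printed vs 0.396/−0.106 count-derived); the package
reproduces the count-derived values and the fixture carries a note.

## Numerical and testing choices

Problem sizes in the test suite — 100 replicates of 1000+1000 subjects for
CI-coverage checks, 10k+10k for the binormal AUC identity, 100k draws for
the HWE mean — were chosen as the smallest sizes at which the Monte-Carlo
error is comfortably below the tolerance being asserted. Oracles
(pair-counting AUC, mover-enumeration NRI, placement-value DeLong, day-step
integration) share no code with the implementation paths they check.

## Known limitations

- Shipped parameter and hazard tables are illustrative; clinical use
  requires calibrated inputs.
- The family-history table is a coarse banding; full pedigree models will
  capture familial risk that a count-based table cannot.
- No ER-subtype-specific SNP effects; the PRS is a single overall score.
- Palindromic (A/T, C/G) SNPs are accepted on allele identity only when
  the risk-allele frequency is informative (|p − 0.5| > 0.1); otherwise
  they are treated missing rather than guessed.
- Competing mortality is all-cause-minus-breast-cancer as a single rate;
  no cohort effects or secular trends.
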