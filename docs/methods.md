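# Methods

## Scope and data model

`pvep` analyses spontaneous adverse-event reports in the FAERS quarterly
ASCII dialect: seven `$`-delimited tables joined on the report id
(primaryid). The normalized `ReportStore` keeps one row per report
(case id, FDA receipt date, sex, age in years, weight in kg, country,
reporting year, event date) plus child tables of drug rows (normalized
name, role code, therapy start date), MedDRA preferred-term (PT) event
rows, and outcome codes. Dates must be full `YYYYMMDD` to participate in
day-level arithmetic; `YYYYMM`/`YYYY` values are retained as missing.
Ages are converted to years from the FAERS unit codes (DEC/YR/MON/WK/DY/HR)
and weights to kilograms (1 lb = 0.45359237 kg). Drug names are uppercased,
trimmed, and stripped of a configurable list of salt/ester suffixes.

## Case definition

A report is an eosinophilic-pneumonia (EP) case iff at least one of its
events belongs to the EP Standardized MedDRA Query (SMQ 20000159) **and**
at least one drug is coded primary suspect. The SMQ nominally contains 15
preferred terms; the shipped default table carries the nine publicly
printed ones (eosinophilic pneumonia 10014962, its acute/chronic variants
10052832/10052833, Löffler's syndrome 10024794, pneumonitis 10035742,
pulmonary eosinophilia 10037382, hypereosinophilic syndrome 10048643,
eosinophilic granulomatosis with polyangiitis 10078117, eosinophilic
pleural effusion 10080148) and is user-extendable. Matching is by PT code
where event rows carry codes, otherwise case-insensitive exact name match.

## Deduplication

Two stages, applied in order and idempotent as a pair:

1. **Case-id rule.** Among reports sharing a case id, keep the most recent
   FDA receipt date; ties go to the largest report id. A missing receipt
   date sorts as older than any dated report (a missing date cannot be
   "most recent").
2. **Demographic rule.** Among survivors, reports identical on (age, sex,
   event date, sorted PT set, sorted primary-suspect set) collapse to the
   largest report id. The PT and suspect sets are part of the key so that
   genuinely different reports filed for demographically similar patients
   are not merged. The rule considers only reports whose key fields are
   all present (age known, sex male/female, event date present): a manual
   deduplication cannot assert that two reports describe the same episode
   on absent fields, and without this restriction the coarse key collapses
   large blocks of unrelated incomplete reports.

## Disproportionality panel

The counting unit is the unique deduplicated report. For drug D the 2×2
table is a = EP reports with D as primary suspect, b = non-EP reports with
D, c = EP reports without D, d = the remainder, so a+b+c+d = N is the
store size. Metrics:

- ROR = ad/bc; 95% CI = exp(ln ROR ± 1.96·s), s = √(1/a+1/b+1/c+1/d);
- PRR = [a/(a+b)] / [c/(c+d)]; χ² = N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)),
  uncorrected by default (Yates available by flag);
- relative reporting ratio RRR = aN/((a+b)(a+c)) — observed over expected
  under independence; IC = log₂ RRR; IC025 = IC − 1.96·s/ln 2 (delta
  method on the log₂ scale);
- EBGM = RRR with EBGM05 = exp(ln EBGM − 1.64·s), a one-sided 95% bound.

The IC and EBGM here are the simplified observed/expected forms, not the
full Bayesian shrinkage estimators (gamma-Poisson/MGPS hyperparameter
estimation is deliberately out of scope; the panel interface leaves room
to slot those in). With any zero cell the ratio metrics are returned as
NaN and flagged rather than silently corrected; an optional
Haldane–Anscombe mode adds 0.5 to every cell for the ratio metrics only.
The Fisher exact p (scipy, two-sided) is always computed on the raw cells.

Positivity follows the conventional any-of rule: PRR-positive
(a ≥ 3 ∧ PRR ≥ 2 ∧ χ² ≥ 4), ROR-positive (95% lower bound > 1),
IC-positive (IC025 > 0). Screening p-values are Bonferroni-adjusted;
Benjamini–Hochberg values are emitted alongside for volcano displays.
Both volcano axis layouts (log₂ROR vs −log₁₀p and its transpose) are just
the two columns of the same export.

## Time to onset

TTO = event date − therapy start date, in whole days, per (case report,
primary-suspect drug); records with a missing/partial date or TTO ≤ 0 are
excluded and the audit conserves counts exactly. Drug-level fits use one
record per (case, drug); subgroup analyses use one record per case
(earliest start date) so patients are not double counted.

Onset laws are fit by uncensored Weibull maximum likelihood — censoring
is structurally absent because only realized events are reported. The
shape equation is solved by bracketed root finding on a profile rescaled
by the sample maximum (numerically safe across β ∈ [10⁻³, 10³]); the
scale has the closed form α = (mean xᵝ)^{1/β}. 95% CIs come from the
delta method on (log α, log β) with a finite-difference observed
information. Constant samples are refused (β diverges). Reported medians
and IQRs are empirical (linear-interpolation percentiles); the parametric
median α(ln 2)^{1/β} is exposed separately.

Failure typing uses the point rule by default — β < 1 early failure
(decreasing hazard, onsets cluster early), β > 1 wear-out, β = 1 random —
because published classifications of this kind type drugs whose CI
crosses 1 by the point estimate; a conservative CI rule is available.
Kaplan–Meier cumulative incidence is computed with lifelines and, with no
censoring, equals the empirical CDF (asserted in tests). Subgroup
comparisons use the tie-corrected Kruskal–Wallis H with a χ²(k−1)
reference; if every pooled value is identical the test returns (0, 1).

## Risk-factor cascade

- **Univariate screen:** keep drugs with ≥ 3 reports (strict > 3
  available), ROR 95% lower bound > 1, and Bonferroni-adjusted Fisher
  p < 0.01 (threshold configurable per stage).
- **Design matrix:** one row per report; candidate-drug indicators
  (1 iff primary suspect), age in years, male sex indicator, weight in
  kg, and a polypharmacy count (distinct drug names on the report, any
  role). Complete-case handling by default; an indicator-plus-mean-impute
  mode exists because spontaneous reports are mostly missing weight.
- **LASSO:** L1-penalized logistic path over a 20-point geometric λ grid
  from the KKT λ_max down three decades, columns standardized internally
  and coefficients reported on the original scale, 10-fold CV stratified
  by outcome, criterion = mean squared error of predicted probabilities
  (binomial deviance by flag), λ at the CV minimum. liblinear penalizes
  the intercept, so a large `intercept_scaling` makes that penalty
  negligible; λ = 0 falls back to an exact unpenalized fit.
- **Final model:** unpenalized maximum-likelihood logistic on the selected
  variables, Wald 95% CIs, per-term Bonferroni adjustment over the number
  of reported terms (the intercept is fit, not reported). Collinear
  columns are dropped with a warning; separated terms are flagged and
  reported with an infinite-CI marker rather than a fake interval.

## Synthetic cohort: what it emulates, and what it does not

Each synthetic report draws demographics from configurable mixtures
(defaults: sex 35.5/49.3/15.2% M/F/unknown, age mass concentrated at
45–74, weight ≈ N(75, 16) kg, country mix dominated by US/JP/CA/EU),
one primary-suspect drug (configured `DrugSpec`s by marginal prevalence,
remainder spread over background drugs), and the EP event as a Bernoulli
whose odds against the background stratum equal the drug's planted
multiplier — the generator plants *odds ratios vs background*, the same
estimand the 2×2 panel targets. EP reports draw their onset from the
drug's planted Weibull law; event date = start date + onset, receipt
follows with a 0–90 day lag inside a 2014–2025 accrual window. MCAR
missingness defaults (age 35%, weight 72%, start/event dates 60% each,
≈ 84% of cases unusable for onset analysis) mirror the heavy
incompleteness of real spontaneous data; an optional MAR mode makes older
reports likelier to lack dates. A configurable fraction of reports
(default 10%) is cloned with a new report id, the same case id and a
later receipt date, so deduplication must restore the pre-injection count
exactly.

Two structural caveats bound what a green test establishes. First, the
planted multiplier is an odds ratio against *background-drug* reports;
the marginal 2×2 comparator ("all other drugs") includes the other
planted drugs, so strong co-planted signals deflate each other's marginal
ROR slightly — the final logistic model, whose reference stratum is
clean, recovers the planted value. Planted-recovery scenarios therefore
keep expected case cells ≥ 30 (the generator's stated operating regime)
and, like real reporting data, tend to put the strongest multipliers on
the rarer drugs. Second, the generator does not imitate free-text drug
name noise, multi-drug regimens (one suspect per report by default),
country-specific reporting cultures, or secular reporting trends; green
tests certify the estimators and the plumbing, not robustness to those
artifacts.

## Numerical and design choices

- Printed percentages use decimal round-half-up at one decimal, matching
  published table formatting; this is why summary percentages over
  exhaustive bins sum to 100.0 ± 0.1.
- Bonferroni is the default screening adjustment; BH is emitted in
  parallel rather than guessed to be "the" adjustment.
- The one-sided 1.64 factor in EBGM05 (not 1.645) follows the convention
  used in published panels of this form.
- Zero adjusted p-values are floored at the smallest positive double
  before the volcano log.
- Pipeline stages derive their seeds from the global seed by hashing the
  stage name (CRC32, mod 2³¹), so any stage can be re-run in isolation
  and reproduced exactly.
- Ranks in Kruskal–Wallis use midranks with the standard tie correction.

## Known limitations

- No MGPS/BCPNN shrinkage variants of EBGM/IC; the simplified forms are
  what the panel reports.
- No censoring, competing risks, or interval-censored onset modelling.
- No masking-effect correction or time-scan methods in the
  disproportionality stage.
- Second-source comparison assumes both sources arrive in the same
  canonical schema; there is no ICSR XML ingestion.
- The LASSO stage's CV-MSE curve is very flat for rare outcomes, so the
  CV-minimum λ is liberal about weak null coefficients; the final
  Bonferroni-adjusted logistic model is the stage that controls the
  reported error rate.
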