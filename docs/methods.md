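# Methods

`faerspv` implements a complete pharmacovigilance study workflow for
FAERS-style spontaneous-report data — cleaning, case finding,
disproportionality signal detection, onset/dose characterisation and
logistic risk modelling — together with a synthetic report generator that
plants known effects so every stage can be validated end to end.

## Data model and cleaning

Quarterly bundles consist of six "$"-delimited tables (DEMO, DRUG, REAC,
THER, INDI, OUTC) linked by report id. A *case* may appear as several
report versions (initial and follow-ups); the case id is the report id of
the first version. Ages are normalised to years (DEC ×10, MON ÷12,
DY ÷365.25, WK ÷52.18), weights to kg (LBS ×0.4536); weights outside
(0, 500) kg are flagged implausible and treated as missing. Partial dates
are imputed to interval midpoints (YYYYMM → 15th, YYYY → 1 July), keeping
the original precision — the midpoint minimises the expected error of
interval arithmetic and keeps onset analysis defined on partial dates.

Cleaning proceeds in three idempotent, order-independent stages:

1. **Single missing-value imputation.** Within a case, a version missing
   exactly one of {event date, age, sex, reporter country} receives the
   *maximum* of that field among the case's fully populated versions.
   Versions missing two or more of the four fields are never imputed.
2. **Two-step de-duplication.** Step 1 collapses versions identical on
   (case id, initial/follow-up code, event date, age, sex, country,
   sorted drug-name set, sorted outcome set); step 2 collapses reports —
   across cases — identical on (event date, age, sex, country, sorted
   drug-name set, sorted reaction set). "Most recent version" is
   operationalised as the largest numeric report id, which the source
   database assigns monotonically; this is robust when event dates are
   partial. Step 1 is version-level (it carries the case id and outcome
   set); step 2 must run after version collapse because it compares
   reaction-linked fields across cases.
3. **Exclusions.** Reports with known age < 18 years are removed; unknown
   ages are retained (demographic tables keep an "Unknown" age stratum).

The study set comprises reports whose *primary-suspect* (role code PS)
drug matches the bundled ALK-TKI synonym table (generic + brand names,
case-insensitive). Concomitant drugs are matched by exact lowercase name;
full vocabulary standardisation is out of scope.

## Case finding

A Standardised MedDRA Query (SMQ) defines the event: a report is a case
iff at least one of its reaction PTs belongs to the query, counted once
per report. The bundled interstitial-lung-disease query (20000042)
carries the six narrow-scope PTs — acute interstitial pneumonitis
(10066728), idiopathic interstitial pneumonia (10078268), interstitial
lung abnormality (10087834), interstitial lung disease (10022611),
pneumonitis (10035742), pulmonary fibrosis (10037383) — plus broad-scope
extras; both scopes are included by default and a switch restricts to
narrow. Report-level counting feeds the 2×2 tables; per-PT counts are
produced separately for the per-PT signal profile.

## Disproportionality statistics

For a drug–event pair, the cleaned universe is partitioned into
a (drug & event), b (drug only), c (event only), d (neither); N = a+b+c+d
and E = (a+b)(a+c)/N.

* **ROR** = ad/bc with Wald 95% CI exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
  A zero cell yields an undefined marker unless the 0.5 continuity
  correction is enabled (the default; applied to ROR only).
* **PRR** = [a/(a+b)]/[c/(c+d)] with Pearson χ² =
  N(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)]; no Yates correction by default, a
  switch enables it for sensitivity analyses.
* **IC** (BCPNN) = log₂[(a+0.5)/(E+0.5)];
  IC025 = IC − 3.3(a+0.5)^−1/2 − 2(a+0.5)^−3/2.
* **EBGM** (MGPS): counts follow a ~ Poisson(λE) with
  λ ~ p·Gamma(α₁,β₁) + (1−p)·Gamma(α₂,β₂). The hyperparameters are
  fitted by maximising the negative-binomial-mixture marginal likelihood
  over *all* drug–event pairs of the database, by L-BFGS on log/logit
  scale from eight deterministic starts (the classic shrinker defaults
  α₁=0.2, β₁=0.1, α₂=2, β₂=4, p=1/3 plus seven perturbations). The
  posterior is again a two-component gamma mixture with components
  (αₖ+a, βₖ+E) and weights proportional to prior weight × marginal;
  EBGM = 2^{E[log₂λ | a,E]} and EB05/EB95 come from root-finding on the
  mixture CDF. Tests verify the implementation against a brute-force
  quadrature of the posterior on a 20,000-point log grid to 10⁻³, and
  invariance under swapping the two mixture components.

The joint signal criterion is a ≥ 3 **and** ROR lower CI > 1 **and**
PRR ≥ 2 with χ² ≥ 4 **and** IC025 > 0 **and** EB05 > 2; per-algorithm
flags are also reported. Published analyses rarely state their exact
thresholds; these are the field's standard defaults and configurable.

## Onset and cumulative dose

Time to onset is event date minus the *earliest* therapy start of the
suspect drug, in whole days; negative intervals are logged as anomalies
and treated as missing. Quartiles use linear interpolation on the sorted
sample (`numpy.percentile` default); 4 weeks = 28 days and
8 weeks = 56 days exactly; fractions are over records with known onset
only. Cumulative dose at onset is daily dose (mg/day) × onset time
(days) ÷ weight (kg) — the computation behind published mg/kg values is
not standardised; this rate×time÷weight definition is the package's
choice.

## Risk model and nomogram

Among study reports, the outcome is the SMQ case flag and the covariates
are: age group (reference 18–64; 65–84; ≥85 — age 85 joins the upper
group; unknown), sex (female, unknown; male reference), the study drugs
(lorlatinib reference), concomitant-disease indicators derived from the
indication PTs of *non-suspect* drugs (spontaneous reports carry no
comorbidity table), and concomitant-drug indicators from non-suspect
DRUG rows. Univariate odds ratios are the 2×2 cross-products with Woolf
CIs (identical to a single-covariate logistic fit). The multivariable
fit is maximum-likelihood logistic regression (statsmodels IRLS);
constant and exactly aliased columns (QR rank check) are dropped with a
warning; quasi-separated likelihoods that break Newton's Hessian solve
are refitted with L-BFGS; perfect separation raises an error naming an
offending covariate. Wald p-values are reported throughout.

The nomogram assigns each covariate points
100·(βx − min_range(βx))/max_j range_j(βx), so the covariate with the
largest |β|·range spans exactly 100 points and negative coefficients
award their points at the low end — this keeps the total-points →
probability curve monotone and makes the mapping exactly invertible:
probability = expit(base + scale·points/100) with
base = intercept + Σ min(βx). Round-trip equality with the model's
direct prediction is exact (tested to 10⁻⁶).

## Synthetic data generator

The generator emulates the features of spontaneous-report data that the
pipeline must survive: multiple case versions (exact duplicates and
follow-ups), missing demographics, partial dates, age/weight units (MON,
DEC, LBS), brand-name drug strings, one primary suspect per report with
concomitants, indication rows, outcome codes, and log-normal onset
models per drug. All randomness flows from an integer-seeded generator;
identical (config, seed) yields byte-identical files.

Planted structure and defaults (the study conditions):

* Five ALK TKIs with use probabilities proportional to the real-world
  report shares (crizotinib 0.0455 … lorlatinib 0.0124) and label daily
  doses (500/450/1200/180/100 mg).
* Six ILD preferred terms with background probabilities totalling
  ≈ 0.012 and per-drug planted relative risks (crizotinib 4.6,
  ceritinib 3.7, alectinib 4.7, brigatinib 6.2, lorlatinib 2.5).
  Background rates are scaled up relative to the real database so that
  desk-scale runs (50–60k reports rather than 13M) retain adequate
  counts; shares of ILD among study reports are therefore higher than in
  the real data and are not a comparison target.
* Per-drug log-normal onset models with medians 29/70/49/7/36 days and
  σ = 1.8 (matching the broad reported interquartile spread).
* Concomitant drugs with planted *report-level* odds ratios on ILD
  (amlodipine 10.1, magnesium oxide 33.7, lansoprazole 9.8,
  pantoprazole 4.9, …) and a female excess of 2.2. Baseline per-PT
  events are drawn first; an exact union-level augmentation/thinning
  step then moves the report-level occurrence probability to
  expit(logit(p_union) + Σx·lnOR). When all modifiers are 1 the
  baseline mechanism is untouched, so null and single-signal
  configurations plant per-PT relative risks exactly.
* Indications are recorded with probability 0.7 — spontaneous reports
  have notoriously incomplete indication fields, and perfect recording
  would make the disease indicators deterministic functions of the
  concomitant-drug indicators, a degeneracy real data does not have.
* Duplicate rate 0.05 (exact copies, new larger report id), follow-up
  rate 0.10 (fully populated versions flagged "F"), field missingness
  0.02–0.30, partial-date rate 0.05, 2% under-18 reports.

A truth ledger records per-report planted values (true demographics,
suspect drug, event occurrence, onset days, blanking and duplication
flags) and exact injection counts, so cleaning results can be checked
exactly and covariate prevalences against exact binomial bounds.

What the generator does **not** emulate: free-text drug-name noise
(misspellings), MedDRA hierarchy beyond the PT level, reporting-date
dynamics, stratified background rates (age/sex-specific event
frequencies) and exposure information. Passing tests therefore
demonstrate correctness of the algorithms under the planted model, not
calibration of real-world signal strengths.

## Numerical and testing choices

* MGPS convergence: best of eight deterministic starts; likelihood
  tolerance 10⁻¹² (ftol), gradient 10⁻⁸; an unconverged prior makes
  EBGM refuse with a diagnostic rather than return silently shrunk
  values.
* EBGM quantiles: Brent root-finding on the exact mixture CDF, bracketed
  by component quantiles, xtol 10⁻¹².
* Percentages destined for tables use decimal half-up rounding (6.875 →
  6.9), matching published-table conventions, rather than banker's
  rounding.
* De-duplication keys treat missing fields as the empty string; ties are
  broken by report id, never by input order (shuffling the input changes
  nothing).
* Calibration checks run at desk scale: twenty 50,000-report null
  databases for the false-positive bound (≤ 5% of pairs under the joint
  criterion), twenty seeds for the power of a planted RR = 5 pair
  (ROR-flagged in ≥ 80%), and twenty n = 20,000 logistic simulations for
  coefficient recovery (mean absolute bias < 0.05). Interval coverage of
  the null ROR is assessed over pairs with a ≥ 3, where the Wald
  interval's nominal level is meaningful (it is known to undercover at
  a ∈ {1, 2}).

## Known limitations

* Step-2 de-duplication can collapse genuinely distinct reports that
  coincide on all six key fields (≈ 1 in 5,000 at desk scale); this is
  the rule's intended behaviour, and counts are reported separately per
  step.
* The Wald p-values of the multivariable fit disagree with some
  published analyses whose test is unstated; the univariate/multivariate
  odds ratios themselves are the reproducible quantities.
* The MGPS prior is unstratified (no age/sex strata) and single-item
  (no drug–drug interaction terms).
* With very strong planted odds ratios and modest study sets the
  logistic likelihood can be quasi-separated; estimates are then finite
  but unstable, which the L-BFGS fallback reports honestly through wide
  Wald intervals.
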