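# Methods

## Scope and data model

The pipeline operates on spontaneous adverse-event reports in the style of
the FDA Adverse Event Reporting System (FAERS): one case report carries
demographics (sex, age, weight — each frequently missing), reporter
occupation, country, a list of drug records (name, suspect/concomitant
role, start date, indication), a list of event preferred terms (PTs), a set
of seriousness outcomes, and an event onset date. Two dialects are read:
the quarterly `$`-delimited ASCII tables (DEMO/DRUG/REAC/OUTC/THER joined
on `primaryid`) and a flat `simple_csv` dialect (one row per report × drug
× event) that the synthetic generator writes losslessly.

Curation follows standard FAERS practice. The duplicate key is the case
identifier alone and the latest receipt date wins (ties: highest version,
then first occurrence). "Incomplete" means no drug record or no reaction
record, or a receipt year outside the configured 2004–2025 window;
demographic missingness never excludes a report at this stage — that is
deliberately deferred to the complete-case sensitivity analysis, because
cohort tables in this field retain "Unknown" rows. Drug names are
normalized by uppercasing, whitespace collapse, and stripping a
configurable list of trailing salt suffixes; no external dictionary is
used. Event matching is exact on the normalized PT (never substring, so
"Cheilitis" does not capture "Cheilitis angular"), optionally widened by an
explicit synonym list. Partial dates use conventional midpoints (YYYYMM →
day 15, YYYY → July 1).

## Disproportionality

The unit of counting is the report: a drug or term repeated within one
report contributes once. All drug roles count toward exposure by default
(`roles="suspect_only"` restricts to primary/secondary suspects); the
field's practice varies and the choice is surfaced rather than hidden.

ROR and PRR use the closed forms with 95% log-scale (Woolf) intervals; the
chi-square is Pearson's with Yates correction by default (the usual partner
of the PRR rule), delegated to `scipy.stats.chi2_contingency`. Zero-cell
policy: when a > 0 but b, c or d is zero, the Haldane–Anscombe +0.5
correction is applied to all four cells for both the estimate and the
interval; pairs with a = 0 are reported with a zero sentinel and can never
be flagged. This is the dominant convention; the alternative (correcting
only the CI) changes nothing qualitatively and is not offered.

The empirical-Bayes shrinker is the DuMouchel gamma-Poisson model.
Expected counts E are crude (unstratified) by default;
`stratified_cells()` provides Mantel–Haenszel-style within-stratum
expectations summed over strata, with reports missing the stratification
variable forming their own "unknown" stratum. Hyperparameters are fitted
by maximizing the marginal likelihood (a two-component negative-binomial
mixture) over all cells with n ≥ 1, untruncated by default with the
n ≥ 1-truncated likelihood available as an option. Optimization is
L-BFGS-B over (log α₁, log β₁, log α₂, log β₂, logit P) from five fixed
starts, the classical (0.2, 0.1, 2, 4, 1/3) first; the best optimum is
kept, components are canonically ordered by prior mean, and the fit is
rejected if it fails to reach the likelihood of the classical start.
Hyperparameters are bounded at 1e5 on each gamma parameter: on corpora
where almost every pair is truly null the MLE pushes one component toward
a point mass at λ = 1, and the bound keeps the fit finite without
materially changing the likelihood. EBGM is exp(E[ln λ | n]), evaluated
with the digamma function on the conjugate posterior mixture; EB05/EB95
come from monotone root-finding (Brent) on the posterior CDF, with the
bracket taken from the component quantiles and padded against
floating-point slack. The test suite checks the conjugate implementation
against brute-force numerical integration of the posterior density in
ln λ space (the substitution removes the λ → 0 singularity when a shape
is below 1) on a 45-point grid; agreement is at the 1e-10 level, far
inside the 1e-4 contract.

Signal rules default to: ROR rule (n ≥ 3 and ROR CI low > 1), PRR rule
(PRR ≥ 2, χ² ≥ 4, n ≥ 3), EBGM rule (EB05 > 2). Where a single "signal"
notion is needed (concordance, flag rates) the ROR rule is the default and
the flag is a parameter.

## Subgroups and sensitivity

Subgroup analyses rerun the full pipeline inside each stratum of age
(<19, 19–44, 45–59, ≥60 years — half-open intervals resolve the published
tables' overlapping labels), sex, or weight (<50, [50, 100], >100 kg; both
50 and 100 kg belong to the middle bin). Pairs with fewer than
`min_cases = 3` reports in a stratum are omitted — small-count subgroup
estimates are statistically unstable, and three cases is the conventional
floor. The complete-case sensitivity analysis keeps exactly the reports
with age, sex and weight all present and repeats the primary analysis;
the concordance report counts pairs flagged in both, with the retention
fraction defined against the primary signals (zero when the primary
analysis flagged nothing).

## Risk-factor model

The design is complete-case: cohort (outcome 1) versus all other
background reports (outcome 0); covariates are sex (female = 0 / male = 1,
always reported with the coding because OR directions for sex are
ambiguous without it), age and weight per unit and untransformed,
indicators for the 20 most frequent normalized indication terms in the
background (the operational stand-in for "most prevalent comorbidities"),
and indicators for screened drugs. Logistic fits use iteratively
reweighted least squares with step-halving (log-likelihood never
decreases), converging at max |score| < 1e-8 or relative deviance change
< 1e-10; complete separation is reported as an error naming the diverging
term (|β| > 15 with a non-vanishing score), rank deficiency as an error
naming the collinear columns. Stepwise selection is forward with backward
pruning driven by likelihood-ratio tests (better behaved than Wald at
small counts) at a fixed alpha, deterministic for a fixed candidate order,
with a full add/drop trace; the reported per-term intervals are Wald, the
field's display convention.

## Descriptives

Percentages are rounded half-up to two decimals. Each variable block is
divided by the sum of its own rows (for blocks whose rows cover every case
this equals the cohort size); outcomes are divided by the total number of
outcome mentions, since one report can carry several; countries by the
number of reports with a known country. These conventions are the ones
under which the published cheilitis cohort table's printed percentages
reproduce exactly from its printed counts — the one exception is the
"Other" country row, which the source prints as the complement of the
named rows' rounded percentages rather than a directly rounded ratio.
Time-to-onset is the whole-day difference between the event onset date and
the earliest suspect-drug start date; negative or incomputable values are
unknown; bins are closed-left ([2, 5) so day 2 is "2–5", day 28 is "≥28").

## Synthetic generator

The generator emulates the joint structure the pipeline consumes:
demographics with realistic missingness (weight 66%, age 27%, sex 6.6%,
TTO 47%, country 28%, missing completely at random), a zero-truncated
Poisson number of drugs drawn without replacement from a Zipf-like
popularity vector, independent per-event occurrence with configurable base
rates, reporter/country/outcome categoricals with field-typical shares,
and dates giving a lognormal time-to-onset (median 15 days by default).
Associations are planted as odds multipliers θ on specific drug-event
pairs, so the crude ROR is the exact estimand of a recovery test; planted
covariate effects (log-odds on sex/age/weight) act on the target event
only, keeping them identifiable in the case/background design. Reports
realizing zero events are rejected and resampled — a spontaneous report
always carries a reaction — and this conditioning provably leaves the
exposure-event odds ratio at θ, because the discarded reports deplete the
drug/no-event and no-drug/no-event cells by the same factor. Everything
derives from a single numpy generator: one seed, byte-identical corpora.

What the generator does **not** emulate: MedDRA hierarchies, real
co-prescription structure (drugs are sampled independently of
demographics), event-event correlation beyond shared drugs, reporting
trends over calendar time, duplicate submissions, or any
missing-not-at-random mechanism. Passing recovery tests therefore
demonstrate correctness of the estimators under MCAR missingness and
independent exposures — not robustness to the confounding and reporting
artifacts of real spontaneous data.

## Problem sizes and tolerances

The recovery suites use 20 replicate corpora of 50,000 reports for the
planted-association and complete-case checks, 5,000 cells for
hyperparameter recovery (tolerance 0.5 on each log hyperparameter, ±0.15
on the mixture weight, after canonical component ordering), 200 all-null
and 100 strong-predictor runs for the stepwise operating characteristics,
and a 45-point (n, E, prior) grid at 1e-4 relative tolerance for the
shrinker oracle — sizes chosen so the whole suite runs in minutes on one
CPU while leaving each check's Monte Carlo error well inside its margin.

## Known limitations

- The mixture-likelihood surface is multimodal; five fixed starts suffice
  on every tested corpus but a pathological corpus could require more
  (`fit_prior(starts=...)`).
- On corpora dominated by truly-null pairs with large expected counts the
  fitted prior concentrates near λ = 1 and EBGM shrinks genuinely strong
  outlier pairs hard; the frequentist metrics are unaffected and the EBGM
  rule stays conservative (this is inherent to empirical Bayes, not a
  defect).
- Stepwise selection inherits the usual caveats (post-selection inference
  is not corrected; reported p-values are conditional on the selected
  model).
- The FAERS ASCII reader covers the DEMO/DRUG/REAC/OUTC/THER columns the
  pipeline needs, not the full quarterly schema (no INDI/RPSR tables;
  indications are read from the DRUG table's `indi_pt` column when
  present).
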