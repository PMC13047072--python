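# cheilitis-pv

Pharmacovigilance signal detection for **drug-induced cheilitis** from
spontaneous adverse-event reports, built as a reusable, fully tested
pipeline: FAERS-style report curation, disproportionality analysis
(ROR, PRR, chi-square, and the DuMouchel gamma-Poisson EBGM shrinker),
subgroup and complete-case sensitivity analyses, stepwise logistic
risk-factor modelling, and cohort descriptives. A synthetic report
generator with *planted* drug-event associations makes every stage
testable without downloading a single quarterly file.

It is written for pharmacoepidemiologists and methodologists who want the
standard signal-detection stack as inspectable, scriptable Python rather
than a black box.

## The statistics

For a drug-event pair, the corpus of N deduplicated reports splits into the
2x2 table (a, b, c, d): a reports with both, b with the drug only, c with
the event only, d with neither. The package computes

- **ROR** = (a d)/(b c), with the Woolf interval
  exp(ln ROR ± 1.96 √(1/a + 1/b + 1/c + 1/d));
- **PRR** = [a/(a+b)] / [c/(c+d)] with its log-scale interval, and the
  Pearson chi-square (Yates-corrected by default);
- **EBGM**: the relative reporting rate λ = n/E (E = (a+b)(a+c)/N, the
  count expected under independence) receives a two-component gamma mixture
  prior λ ~ P·Gamma(α₁, β₁) + (1−P)·Gamma(α₂, β₂), whose five
  hyperparameters are fitted by maximizing the marginal
  negative-binomial-mixture likelihood over all (n, E) cells. The posterior
  is again a gamma mixture; EBGM = exp(E[ln λ | n]) and EB05/EB95 are its
  5th/95th percentiles.

Default signal rules (all thresholds configurable): ROR rule n ≥ 3 and CI
lower bound > 1; PRR rule PRR ≥ 2, chi-square ≥ 4, n ≥ 3; EBGM rule
EB05 > 2.

Risk factors are screened univariately and selected by stepwise logistic
regression (forward with backward pruning on likelihood-ratio tests at
alpha = 0.05), reporting Wald OR intervals. Sex is coded female = 0 /
male = 1 — stated here because published OR directions for sex are easy to
misread without the coding.

## Worked example

The analysis scripts run the whole pipeline on a simulated corpus with
three planted cheilitis associations (odds multipliers 12, 5 and 2):

```bash
python analysis/01_simulate_corpus.py --n-reports 20000 --seed 42
python analysis/02_curate_reports.py
python analysis/03_detect_signals.py
python analysis/04_subgroups_and_sensitivity.py
python analysis/05_risk_factors.py
python analysis/06_describe_cohort.py
```

which prints (abridged):

```
600 pairs with n >= 3; 3 flagged for 'Cheilitis':
  DRUG_001: n=3011 ROR=10.11 (9.38-10.89) EBGM=2.39 [ebgm_signal;prr_signal;ror_signal]
  DRUG_004: n=933 ROR=2.81 (2.56-3.08) EBGM=1.84 [prr_signal;ror_signal]
  DRUG_009: n=311 ROR=1.35 (1.18-1.55) EBGM=1.08 [ror_signal]
...
stepwise (alpha=0.05) selected: ['drug:DRUG_001', 'drug:DRUG_004', 'drug:DRUG_009', 'age_years', 'sex_male']
  drug:DRUG_001: OR=13.294 (11.224-15.745) p=9.4e-233
  drug:DRUG_004: OR=4.579 (3.642-5.756) p=1e-37
  drug:DRUG_009: OR=2.320 (1.684-3.198) p=6.2e-07
  age_years: OR=0.992 (0.989-0.996) p=1.3e-06
  sex_male: OR=0.708 (0.597-0.840) p=6.7e-05
```

All three planted drugs are flagged. The *crude* RORs sit below the planted
multipliers because the other planted drugs inflate the event rate among
the "unexposed" reports; the *multivariate* ORs, which adjust for
co-exposure, land on the planted values (13.3 / 4.6 / 2.3 against 12 / 5 /
2) — exactly the crude-vs-adjusted gap the risk model exists to close. The
sex and age ORs recover the planted log-odds effects (e.g. exp(-0.26) =
0.77 vs the fitted 0.71). Outputs land in `results/` as CSV/JSON.

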