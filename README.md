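# pesival

Validation toolkit for mortality-risk scores in critically ill patients
who develop **secondary pulmonary embolism** (PE diagnosed after ICU
admission for another critical illness).

Patients with secondary PE sit at the intersection of two prognostic
traditions: general ICU severity scores (APACHE-IV) and PE-specific
scores designed for primary PE — the Pulmonary Embolism Severity Index
(PESI), its simplified form (sPESI), and the ICU-adapted extension
(ICU-sPESI). `pesival` implements the full validation workflow for this
population as a tested, reproducible library plus CLI:

* **Score calculators.** PESI (one point per year of age plus fixed
  points: 10 = male sex, heart-failure or chronic-lung-disease history;
  20 = heart rate ≥110/min, respiratory rate ≥30/min, temperature
  <36.0 °C, SaO₂ <90%; 30 = cancer history, systolic BP <100 mmHg;
  60 = altered mental status), sPESI (six one-point criteria, age
  strictly >80), ICU-sPESI (sPESI + intubation, altered mental status,
  vasoactive infusion; classes I–IV at ≤2 / 3–4 / 5–6 / ≥7 points).
  APACHE-IV is consumed precomputed.
* **Vitals preprocessing.** Raw time-stamped vital signs are reduced to
  medians over tumbling 30-minute windows; the most aberrant window
  median per channel (maximum for heart and respiratory rate, minimum
  for blood pressure, temperature and saturation) feeds the scores.
* **Cohort selection.** Secondary-PE inclusion (PE entry on the running
  diagnosis list within 48 h of admission, not present on admission) and
  exclusion of admission diagnoses suggestive of primary PE.
* **Validation statistics.** Univariate logistic models; AUROC with the
  Hanley–McNeil standard error and the paired Hanley–McNeil z-test for
  correlated AUROCs; calibration tables by score deciles or distinct
  values; Wald binomial confidence intervals; two-group comparisons with
  conventional test selection.
* **Survival analysis.** Kaplan–Meier curves per score class with
  administrative censoring at 55 days, multi-group log-rank and
  Bonferroni-adjusted pairwise tests.
* **Synthetic cohort generator.** A latent-severity factor model that
  emulates the statistical structure of a real secondary-PE ICU cohort
  (criterion prevalences, class-conditional mortality, log-normal death
  times), so the entire pipeline is exercisable without access-controlled
  patient data.

## Worked example

```sh
pesival run-all --n 1000 --seed 1 --outdir out/
cat out/report.txt
```

prints (abridged):

```
cohort n = 1000, deaths = 206
in-hospital mortality 20.6% [95% CI 18.1%-23.1%]

AUROC (Hanley-McNeil SE):
  apache_iv  0.728 (SE 0.021)
  pesi       0.707 (SE 0.022)
  spesi      0.636 (SE 0.023)
  icu_spesi  0.699 (SE 0.022)

paired AUROC comparisons:
  apache_iv_vs_spesi       delta +0.092  p 0.000
  pesi_vs_spesi            delta +0.071  p 0.000
  spesi_vs_icu_spesi       delta -0.063  p 0.000
  ...

mortality by icu_spesi_class:
  I    n=478   deaths=45   9.4%
  II   n=352   deaths=91   25.9%
  III  n=146   deaths=52   35.6%
  IV   n=24    deaths=18   75.0%
  log-rank chi2 138.34 (df 3), p 8.614e-30
```

The run simulates a 1000-stay cohort, applies the inclusion window and
diagnosis blocklist, rebuilds worst-case vitals from the raw series,
scores every patient, and reports discrimination, calibration and
survival. Here the general-severity APACHE-IV discriminates best
(AUROC 0.728), PESI and ICU-sPESI are close behind, and sPESI is
significantly worse than the other three (all p < 0.001) — the
qualitative pattern expected in this population. ICU-sPESI classes
separate mortality strongly (9.4% in class I up to 75% in class IV).
`out/results.json` carries the same numbers at full precision, and the
intermediate CSVs (cohort, vitals, scores, exclusions) are written
alongside. Reruns with the same seed are byte-identical.

Every stage is also available as its own subcommand (`simulate`,
`select`, `preprocess`, `score`, `validate`, `survival`) and as plain
library functions (`pesival.pesi_score`, `pesival.roc_auc`,
`pesival.km_fit`, ...).

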