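# Methods

## Scope and data model

One row of the cohort table is one ICU stay. All times are relative to
ICU admission (minutes for raw observations, fractional days for
follow-up); there are no calendar dates, matching the de-identified
design of the critical-care registries this workflow targets. Repeat
stays are distinct `patient_id`s. Missing booleans on input are read as
`False` — unrecorded history is treated as uncoded, the usual registry
convention — whereas missing demographics, vitals, APACHE-IV, outcome
or admission diagnosis are *key data*: in strict mode such rows go to an
exclusion report (reason `"missing key data"`) rather than being
silently dropped, so retained records plus exclusions always partition
the input.

## Vital-sign reduction

Scores are computed from the most aberrant vital-sign values of the
stay, where a "value" is the median over a 30-minute window rather than
a single raw measurement (robust to spot artifacts). Two conventions
are deliberately fixed and configurable rather than claimed:

* **Windows are tumbling**, anchored at admission (`[30k, 30(k+1))`
  minutes). Tumbling windows are deterministic and make each
  observation contribute to exactly one median; a sliding convention
  would be underdetermined without a stated stride.
* **The scan horizon defaults to the first 48 h** of the stay, the same
  window used for secondary-PE inclusion (`observation_horizon_hours`).

"Most aberrant" is one-sided per channel in the direction of the score
cut-offs, all of which are one-sided: maximum window median for heart
rate and respiratory rate, minimum for systolic pressure, temperature
and SaO₂. This makes the reduction permutation-invariant, idempotent,
and monotone: the thresholded flag from the worst-case value is exactly
the OR of the per-window flags.

## Score calculators

Every comparator is applied exactly as published: HR ≥ 110/min,
RR ≥ 30/min, T < 36.0 °C, SaO₂ < 90 %, SBP < 100 mmHg, and strict
age > 80 years for the simplified scores; PESI adds `floor(age)` points
(integer years). Boundary tests pin each comparator. Two conventions
are assumptions, documented as such:

* **PESI risk classes** use the original published strata
  (≤65 / 66–85 / 86–105 / 106–125 / >125 → I–V).
* **Chronic cardiopulmonary disease** (sPESI/ICU-sPESI) is its own
  boolean, distinct from the separate heart-failure and
  chronic-lung-disease flags that PESI scores — observed prevalences of
  the combined flag differ from the union of its components, so mapping
  raw comorbidities onto it is the data producer's responsibility.

APACHE-IV is a passthrough: computing it from its 129 raw variables is
out of scope, and it is consumed as reported by the source system.

## Cohort selection

A stay qualifies as secondary PE when a PE entry appears on the running
diagnosis list in the half-open interval (0, 48] hours from admission
and is not the primary admission diagnosis. An entry time-stamped
exactly at admission is treated as present-on-admission (primary PE) —
a documented convention, not a claim about any particular registry's
semantics. Admission diagnoses suggestive of primary PE are excluded by
case-insensitive substring match against a configurable phrase
blocklist; the shipped default contains seven phrases (arterial
thrombus, thrombectomy, embolectomy, vascular thrombosis, atypical and
respiratory chest pain, caval filter insertion). Selection is monotone
in the window length, and blocklist exclusion partitions its input with
a non-empty reason per excluded stay.

## Synthetic cohort generator

The generator's purpose is to produce cohorts with the statistical
structure the validation stack assumes, so that every stage can be
tested end to end without access-controlled patient data.

**Dependence structure.** All binary criteria derive from one standard
Gaussian latent severity factor `L` via a threshold model: criterion
`j` fires when `λ_j L + sqrt(1-λ_j²) ε_j` exceeds the `(1-p_j)` normal
quantile, giving exact marginal prevalence `p_j` and positive pairwise
dependence. Independent criteria were rejected because they cannot
reproduce the heavy upper tail of the observed score distribution (the
very-high-risk class would be nearly empty). Loadings are tiered to
mirror the observed survivor/non-survivor contrasts: comorbidity items
load weakly (0.10–0.15), vital-sign items moderately (0.40–0.45), and
treatment/mental-status items strongly (0.70). The tiering is a free
modelling choice, not an estimate of any real cohort's correlation
matrix.

**Prevalences** default to the target population's: e.g. cancer 22.8 %,
SBP < 100 54.2 %, hypothermia 8.0 %, intubation 36.5 %, altered mental
status 40.4 %, vasoactive infusion 19.5 %. Age is normal with median 66
and SD 17 years (IQR ≈ 53–76), clipped to [18, 90]; under the normal
model P(age > 80) ≈ 0.20, somewhat above the ≈ 0.145 seen in real
cohorts whose age distribution is left-skewed — a known, accepted
simplification. APACHE-IV is `58 + 28·(0.9 L + 0.44 ε)` rounded and
clipped to [0, 220] (median ≈ 56, IQR ≈ 39–77).

**Mortality.** Each patient's realised ICU-sPESI class anchors their
death probability to the class rates (defaults 8.4 / 19.1 / 39.4 /
73.3 % for classes I–IV). Within each class the death logit is
`α_c + γ (L - mean(L))`, with `α_c` solved by root-finding so the
class-average probability equals the configured rate exactly; the
residual severity slope `γ` (`latent_mortality_effect`, default 1.0,
log-odds per latent SD) lets variables that track severity more closely
than the class — APACHE-IV above all — discriminate beyond it. With
`γ = 0` mortality is purely class-conditional, but then the class would
be a sufficient statistic for death, no score could beat ICU-sPESI, and
the qualitative AUROC ranking (APACHE-IV first, sPESI last) seen in
validation studies of this population could not emerge.

**Times.** Death times are log-normal with median 6.2 days and
log-scale σ = 1.4. A single log-normal cannot match both reported
quartiles of real death times (≈ 1.7 and 11.7 days); σ = 1.4 splits the
difference between the values implied by each quartile and keeps the
right skew. Survivors carry the administrative censoring time, 55 days.

**Vitals series.** Each patient gets a small raw series per channel
(three 30-minute windows, odd observation counts so each window median
is an observed value exactly): one window holds the stored worst-case
value, the others strictly less aberrant values on the same side of the
cut-off. Re-running the preprocessing stage on the series therefore
reproduces each record's worst-case vitals and threshold flags exactly
— checked by test.

**Reproducibility.** One integer seed drives a single `numpy`
Generator; identical specs give identical cohorts.

What the generator does **not** emulate: the real joint distribution of
comorbidities and diagnoses beyond the single-factor dependence, the
admission-diagnosis casemix beyond a category label, correlation
between death time and severity, and the left skew of the age
distribution. Tests that pass on synthetic cohorts therefore certify
the pipeline's correctness and internal consistency, not the field
performance of any score on real patients.

## Discrimination and calibration

**AUROC** is the tie-corrected rank statistic (midranks; concordant
pairs plus half the ties over `n_pos · n_neg`), with the Hanley–McNeil
standard error (`Q1 = A/(2-A)`, `Q2 = 2A²/(1+A)`). An exhaustive
pairwise-concordance oracle in the test suite confirms equality on
random instances up to n = 50.

**Paired AUROC comparison.** Two scores measured on the same cases are
compared with `z = (A1 - A2) / sqrt(SE1² + SE2² - 2 r SE1 SE2)`. The
correlation term `r` is a function of the average between-score
correlation (Pearson within non-survivors and within survivors,
averaged; Kendall available) and the average area. It is evaluated by
bilinear interpolation on a grid computed from the binormal ROC model —
both scores jointly Gaussian within each outcome group — under which
`r = (Φ₂(z,z; ρ/2) - A²) / (Φ₂(z,z; 1/2) - A²)` with `z = Φ⁻¹(A)`, the
same model behind the classical published lookup table. The test suite
keeps an independent DeLong implementation as an oracle: on simulated
paired scores the two methods agree in their accept/reject decisions at
α = 0.05 and in p-value to within a few hundredths. Degenerate case:
comparing a score with itself gives r = 1, zero variance, and is
reported as z = 0, p = 1.

**Logistic calibration.** Univariate logistic regression (statsmodels
Newton MLE, max 100 iterations) of death on each score; complete
separation or non-convergence is reported via `converged=False`, never
as a silent divergence. Calibration tables show observed vs mean
predicted mortality either by score deciles (quantile bins, duplicate
edges merged — heavily tied scores yield fewer than ten bins) or by
distinct score values, the natural convention for the few-valued
simplified scores.

**Proportions.** Binomial CIs default to Wald (`p ± z√(p(1-p)/n)`,
truncated to [0,1]) because that is the convention under which the
reference cohort's printed intervals reproduce exactly; Wilson is
available via `method=`. **Two-group tests** follow the conventional
selection rules: chi-square with Yates continuity correction for 2×2
tables (the correction reproduces the reference analyses' printed
p-values), Fisher's exact test when any expected cell count is below 5;
for continuous variables a Shapiro–Wilk gate at α = 0.05 chooses
between the t-test and the Mann–Whitney U test.

## Survival

Kaplan–Meier product-limit curves per score class, with administrative
censoring at 55 days: times beyond the boundary are truncated to it
with the event removed; a death exactly at day 55 still counts as an
event. The k-group log-rank test (k−1 df, discrete/hypergeometric
variance under ties) runs first; pairwise tests over all unordered
pairs follow, each p-value multiplied by the number of pairs in that
family (one score's classes) and capped at 1. lifelines provides the
estimator and test; the suite checks the two-group statistic against a
hand-coded per-event-time `(O−E)²/V` sum, the no-censoring case against
the empirical survival function, and the null rejection rate at
α = 0.05 over 1000 simulations.

## Pipeline and problem sizes

`run-all` chains simulate → select → preprocess → score → validate →
survival, writes every intermediate CSV, a full-precision
`results.json`, a one-decimal `report.txt`, and a log with seed and
versions; identical configurations reproduce byte-identical outputs.
The generator emits decoy patients (late PE, primary PE, no PE) in the
diagnosis table so the selection stage filters something real. Default
problem sizes — 1000 stays for the worked example, 5000 for parameter
recovery and discrimination checks, 1000 replicates for the log-rank
null — are chosen so Monte-Carlo error is small relative to the
tolerances tested (3 binomial SEs) while the whole suite and the
acceptance script each run in well under a minute.

## Known limitations

* The latent single-factor dependence is a convenience; real ICU
  cohorts have richer correlation structure.
* Wald intervals and the binormal `r` grid are conventions chosen for
  fidelity to the reference workflow, not the best modern practice
  (Wilson intervals and DeLong variance are available/kept as options
  or oracles).
* No multivariable modelling, reclassification indices, bootstrap CIs,
  Cox regression or competing-risks analysis — all outside the
  validated workflow.
* "Altered mental status" is consumed as a boolean; how it is
  operationalised (e.g. a GCS threshold) is the data producer's choice.
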