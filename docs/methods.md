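# Methods

`gestrisk` re-implements, as a tested library, a longitudinal preeclampsia
risk analysis over electronic-health-record-style event streams: a
rule-based disease phenotype, gestational-age-censored dataset
construction, bespoke time-series features, multi-family risk models with
imbalance resampling, fairness and calibration evaluation, and additive
attribution. Because real obstetric EHR data cannot be redistributed,
every stage is exercised against a synthetic cohort generator with a
*planted* (known) risk structure, so that each claim the test suite makes
is checkable against ground truth.

## The synthetic world

The generator (`gestrisk.synthetic`) draws one row per pregnancy with
demographics, obstetric history and comorbidities whose marginal rates are
calibrated against published summary counts of a large US delivery cohort
(~101k deliveries, 6.1% preeclampsia incidence); the counts are kept in
`REFERENCE_COHORT`. Case status follows a logistic model

    P(case) = expit(b0 + sum_j beta_j x_j)

with planted log-odds weights `DEFAULT_RISK_COEFFICIENTS` (e.g. chronic
hypertension ln 4, prior preeclampsia 1.25, BMI 0.045 per kg/m²). The
intercept `b0` is solved numerically per cohort so the mean planted risk
equals the configured incidence; the realized case fraction is then
binomial around the target. The true risk, case indicator and onset time
form a *truth sidecar* that no pipeline stage reads — it exists only so
tests and the acceptance script can grade the pipeline.

Longitudinal structure: prenatal visits at gestational weeks
{14, 20, 24, 28, 32, 34, 36, 38} (jittered 0–4 days), 1–3 paired SBP/DBP
readings per visit, urine protein at most visits, and AST/ALT/uric
acid/red-cell panels at weeks 14/28/36. Gestational time is integer
minutes from conception because the phenotype uses hour-scale windows.
Cases draw an onset time after 22 weeks (Beta(2, 1.5) over days 154–280,
skewed to the third trimester) and deliver 3–21 days later; their blood
pressure drifts up mildly from 20 weeks (0.10–0.25 mmHg/day) and
escalates sharply at onset through one of four presentations, with mixture
weights chosen so the case mix matches the published covariate table
directionally (61% proteinuric hypertension, 20% severe-range clusters,
10% hypertensive crisis with abnormal liver enzymes, 9% ICD-documented
HELLP/eclampsia). The onset encounter is constructed so the corresponding
phenotype criterion fires deterministically; in practice phenotype
sensitivity on planted cases is ≈100% and the control false-positive rate
≈0, which is deliberately cleaner than real charts — passing tests show the
machinery is correct, not that real-world phenotyping is this easy.

ICD codes are planted with sensitivity 0.90 and specificity 0.974; at 6.1%
incidence this yields an ICD-only positive predictive value of ≈0.69,
reproducing the published observation that billing codes alone
substantially over-call the disease. False-positive codes are drawn from
the preeclampsia family (642.4/O11/O14.9) so they inflate the ICD-only
comparator without firing the HELLP/eclampsia criteria.

The external-validation stand-in (`generate_external_cohort`) reuses the
generator under a shift: nulliparous-only sampling, covariate-rate deltas,
and a coefficient scale. Halving the planted weights weakens the signal,
so a model trained on the base cohort evaluates lower externally — the
direction, not the magnitude, of the published external drop is the
testable claim.

What the generator does *not* emulate: informative missingness, multi-site
coding heterogeneity, medication effects, measurement-device bias, or
postpartum disease. Missingness rates per lab are configurable guesses
(30–40%) since the reference publication reports none.

## Phenotype

Five criteria over one pregnancy's events (`gestrisk.phenotyping`):
moderate-range BP pair (>140/90, ≥4 h apart) with proteinuria; ≥7
severe-range readings (>160/100) within 2 h; HELLP ICD (642.7/O14.1);
eclampsia ICD (642.6/O15); crisis reading (>170/110) with a
preeclampsia-family ICD or AST > 64 / ALT > 70. Design choices that the
source material leaves open, all configurable:

* thresholds are strict (`>`) with OR semantics across the two BP
  components (hypertension-staging convention); an AND flag exists;
* proteinuria = urine protein/creatinine ≥ 0.3 or a proteinuria diagnosis
  code; it may occur at any time in the pregnancy (the 4-hour clause binds
  only the BP pair);
* AST/ALT: either enzyme above threshold suffices; a both-required flag
  exists;
* ICD matching is by code prefix so family-level codes cover children
  (O14 matches O14.1);
* a criterion makes a case only when it fires at ≥140 days (20 weeks);
* ties between criteria at the same earliest qualifying time go to the
  lower criterion number.

The diagnosis is dated at the first qualifying BP-or-proteinuria
observation for BP-based criteria (the code time for ICD-only criteria) to
avoid the late-coding bias of billing timestamps. Only proteinuria events
at ≥140 days enter that minimum, so a stray first-trimester dipstick
cannot date a second-half disease before the gestational window in which
it is defined.

The sliding-window implementations are checked exactly against brute-force
enumeration of all reading pairs and windows on randomized charts, and
against a fixture suite of hand-built charts (positive, negative and
boundary cases per criterion).

## Censoring and leakage control

For each timepoint t ∈ {14,…,38} weeks, `censor_events` keeps events with
time ≤ t (boundary inclusive: a measurement at the anchoring visit is
available at that visit), and `build_timepoint_dataset` drops pregnancies
delivered or diagnosed strictly before t ("prior to", exclusive of the
boundary day). Labels are the eventual case status. `verify_no_leakage`
re-featurizes the censored stream and compares bit-for-bit with the stored
matrix, flagging any feature whose value depends on post-censor events;
the test suite includes a mutation check that a deliberately corrupted
feature is caught. Train/test partitioning is by patient (all pregnancies
of a patient on one side), with one global split reused at every timepoint
rather than per-timepoint re-splitting, so longitudinal comparisons hold
the population fixed.

## Features

Per series: mean, max, min, median, count; the c3 statistic at lag 2
(`mean of x[t+4]·x[t+2]·x[t]`, normalized by n−2·lag, absent when
n ≤ 2·lag); linear and quadratic coefficients of a polynomial fit on times
centered at the censor point (centering decorrelates the two terms); and,
for blood pressure, per-bin min/max/mean with deltas of consecutive bin
means, the bins being the censor-schedule prefix. Statics cover history,
comorbidities, family history and demographics.

Selection and imputation are strictly train/apply separated and refitted
per timepoint on the development split: columns missing in >95% of
development rows are dropped, remaining gaps take the development median,
a Mann–Whitney rank test with Benjamini–Hochberg control at 0.05 retains
relevant columns (the relevance-table procedure named by the source does
not specify its test; BH is the simplest defensible choice and is
configurable), and iterative VIF pruning (drop the worst column until all
VIF < 10, computed from the inverse correlation matrix, exact-collinear
sets assigned infinite VIF, ties broken by dropping the alphabetically
last name) yields the subset the linear families require.

## Models

Six families: logistic regression, elastic-net logistic, Gaussian naive
Bayes, random forest, gradient-boosted trees (xgboost), and a small MLP
(≤2 hidden layers, ≤64 nodes — the architecture is part of the search
space, not fixed). Standardization precedes the linear/MLP families.
Class imbalance is handled by resampling applied *inside* CV training
folds only, never to validation folds or the test set; random
oversampling is the default, with random undersampling, SMOTE and
borderline-SMOTE (nearest-neighbor convex interpolation, seeded)
available for the comparison experiment. Hyperparameters come from seeded
random search: the family default is candidate 0, ten candidates are
scored by mean AUC over 5-fold stratified CV, ties go to the earlier
candidate, and the winner is refit on the full development matrix. All
fits are deterministic under a fixed seed (the MLP included, via its
seeded initializer).

## Evaluation

AUC is pairwise concordance (ties = ½) with a stratified percentile
bootstrap 95% CI (cases and controls resampled separately; 1,000
replicates by default — the CI method is unstated in the source, and the
bootstrap matches its resampling usage elsewhere). Cutoff sweeps report
sensitivity/specificity/flagged fraction per probability cutoff (flag =
score strictly above cutoff, making the curves monotone by construction).
The guideline comparator implements the aspirin-prophylaxis risk rule
(≥1 high-risk or ≥2 moderate-risk factors) both as the binary rule (for
flag-count comparisons) and as a logistic model restricted to the factor
columns (for ROC comparison); the two sociodemographic guideline items are
generator-provided booleans because the guideline does not operationalize
them. Fairness uses the equalized-opportunity difference (TPR gap between
demographic groups at the 0.5 cutoff) with a two-sided resampling p-value
under the pooled-TPR null obtained by permuting group membership among
cases; the generator is group-symmetric by default, which is what makes
the null-calibration test meaningful (a disparity knob exists but defaults
off). Cohort description tables use Welch t-tests for continuous and
chi-squared tests for categorical variables.

## Attribution

Local accuracy — base value plus the row's attributions equals the model
output — is the invariant every method must satisfy. Gradient-boosted
trees and random forests use a double-precision implementation of the
path-dependent tree Shapley algorithm (`gestrisk._treeshap`,
numba-compiled with a plain-Python fallback): boosters are flattened from
their raw JSON serialization (thresholds parsed through float32 and inputs
rounded the same way so routing matches the booster exactly), forests from
the fitted CART arrays. Margins are evaluated in double precision; they
agree with the booster's own float32 outputs to float32 rounding, and the
per-feature values agree with the booster's native contribution
predictions to ~1e-5 (frozen as a cross-check test). Linear families use
the closed form `coef_j · (z_j − mean background z_j)` on the margin
scale; remaining families use a seeded permutation-sampling estimator on
the probability scale whose telescoping construction keeps additivity
exact regardless of the number of draws. Category shares divide total
mean |attribution| among vital-sign, laboratory, history, family-history,
demographic and other features per timepoint and sum to one.

## Problem sizes and numerical choices

The test suite runs at desk scale chosen to make each property decidable:
incidence calibration and the leakage guard at n = 5,000; planted-risk
recovery at n = 20,000 with 10 search candidates × 5 folds (held-out
logistic AUC within 0.03 of the planted-risk oracle on the same rows);
the gestational trend check at n = 4,000 with default hyperparameters;
fairness null calibration over 200 group-symmetric replicates of 2,000
cases with 200-resample p-values (rejection rate required in
[0.02, 0.08] at α = 0.05). Exact oracles (c3 triple products, polynomial
recovery, VIF duplicate pruning, phenotype brute force) are asserted at
1e-12 where float64 permits and 1e-6 to 1e-9 where a model evaluation is
involved. Degenerate inputs are defined, not guessed: empty series yield
absent statistics with count 0; trends need ≥2 points (≥3 for the
quadratic term); single-class AUC raises; a CV fold with one class
raises rather than silently re-stratifying.

## Known limitations

Planted risk is a single logistic surface — no unobserved heterogeneity,
no time-varying hazard — so absolute AUCs here say nothing about
achievable performance on real cohorts; only the *relations* the suite
asserts (model ≤ oracle, external < internal under shift, later ≥ earlier
timepoints, ICD-only PPV ≪ 1) transfer as qualitative claims. The
phenotype's published accuracy against chart review (88.5% of confirmed
cases) cannot be reproduced without the source records. Severity grading,
superimposed preeclampsia, and postpartum-only disease are out of scope.
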