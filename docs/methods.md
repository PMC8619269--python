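# Methods

## The screening problem

Alpha- and beta-thalassaemia traits are the two common carrier states
behind a microcytic, hypochromic blood picture in high-prevalence regions
of Southeast Asia. Both produce low MCV and MCH on a routine full blood
count; telling them apart normally requires haemoglobin analysis (HbA2
quantitation) and, for alpha-trait, DNA testing. Modern haematology
analyzers additionally report *cell population data* (CPD): per-population
medians of volume, conductivity and multi-angle light scatter. The
reticulocyte lower-median-angle light-scatter channel (MN-LMALS-RET) runs
higher in beta-trait than in alpha-trait, as does the red-cell
distribution width (RDW), while MCH runs lower. The package implements a
composite discriminant built from exactly those three quantities:

    S = MN-LMALS-RET x RDW - MCH

with the decision rule

    S > cutoff        -> beta-thalassaemia trait
    S <= cutoff       -> alpha-thalassaemia trait   (ties go alpha)

The default cutoff is 1742.5, the published operating point. The score
is a screening surrogate: calls are annotations to route samples into
confirmatory testing, never a diagnosis.

## Pipeline stages

1. **Pre-screen** (`scoring.prescreen`): the classical microcytosis
   gate MCH < 27 pg, MCV < 80 fL, RDW > 14 %. The criteria list is
   combined with OR by default (`screen_combination="any"`), the
   conservative reading that misses the fewest carriers; AND is
   configurable. The pre-screen is reported alongside the score rather
   than gating it, so no subject silently disappears.
2. **Scoring and classification** (`scoring`): the composite above.
   The tie at exactly the cutoff goes to the alpha (negative) class
   because the beta call is defined strictly by `score > cutoff`.
   Classical discriminant indices (Mentzer, Shine & Lal, England &
   Fraser, Ehsani, Srivastava, Green & King, RDW index) are emitted for
   comparison output only; their published cutoffs are never applied.
   MAF is carried as an input column and never recomputed.
3. **Development** (`roc_eval`, `pipeline.run_develop`): candidate
   analyzer parameters are shortlisted by a two-sided Welch t-test
   (p < 0.05) and orientation-corrected empirical AUC (> 0.8); no
   multiple-testing correction is applied across candidates — a known
   limitation of the original procedure that is reproduced, not fixed.
   The composite's *form* is fixed; only its cutoff and operating
   characteristics are re-derived from data.
4. **Validation** (`diag_accuracy`, `pipeline.run_validate`): per-group
   score summaries and pairwise interquartile \[Q1, Q3\] overlap across
   all labelled disorder groups, then the alpha-vs-beta 2x2 contingency
   table (beta-trait positive) and sensitivity / specificity / PPV /
   NPV with binomial confidence intervals.

## ROC machinery

* Candidate thresholds are midpoints between consecutive distinct score
  values plus +/-inf sentinels; a subject is called positive when its
  oriented score is strictly above the threshold (consistent with the
  classification tie rule).
* AUC is the Mann-Whitney rank statistic with ties half-credited; it
  equals the trapezoidal area under the empirical ROC polygon exactly,
  and both routes are asserted equal to 1e-12 in tests.
* When a parameter runs higher in the negative class its sign is
  flipped so AUC >= 0.5; the flip is recorded in `orientation` and the
  reported thresholds stay on the raw scale.
* AUC confidence intervals: DeLong structural-component variance by
  default (deterministic); a seeded within-class percentile bootstrap
  (default 2000 replicates) as an alternative for small samples. Both
  are clipped to \[0, 1\]; a perfectly separated sample yields a
  zero-width DeLong interval and a warning.
* Cutoff selection: Youden index (sens + spec - 1) by default, or
  closest-to-top-left; ties break toward higher specificity, then the
  lower threshold — specificity is preferred because a false beta call
  sends a sample into a more expensive confirmatory branch.

## Diagnostic accuracy and confidence intervals

Point estimates are exact count ratios. The default interval is the
Wilson score interval (via statsmodels), with Clopper-Pearson exact and
Wald available. Display values are percentages rounded half-up to two
decimals; the underlying proportions are kept at full precision. The
original report's printed CIs came from a web calculator whose method
is not stated and could not be reproduced by Wilson or Clopper-Pearson
recomputation, so this package treats the four point estimates — not
the printed CIs — as the reproducible quantities. A statistic with a
zero denominator is reported as undefined rather than poisoning the
rest. Non-evaluable subjects are excluded from the table but always
counted in an exclusion tally.

## Synthetic cohorts

No subject-level analyzer data is available; only per-group summary
statistics (n, mean, SD, median, min, max) of the red-cell indices and
of the composite score are published. The generator
(`synthetic_data`) therefore emulates *group marginals*, not real
samples:

* **Marginal family.** Normal truncated at the printed min/max. The
  printed mean/SD describe the observed — hence bounded — data, so the
  underlying location/scale are solved numerically such that the
  *truncated* distribution has the printed moments (naive truncation of
  N(mean, SD) would bias both whenever the bounds clip asymmetrically,
  and measurably inflates the carrier-separation AUC). Where the target
  moments are unreachable inside the truncated-normal family (strongly
  right-skewed summaries with tight bounds, e.g. beta-trait MCV), a
  moment-matched scaled Beta on \[min, max\] is used instead: closed
  form, exact moments, bounded support. An optional lognormal family
  exists for heavily skewed quantities. Printed medians are stored but
  not matched; a mismatch between simulated and printed medians is
  expected for skewed parameters and accepted.
* **score_mode** draws the composite score directly from its group
  summary, draws RDW and MCH from the group marginals, and back-fills
  the scatter channel as `(score + mch) / rdw`, so re-scoring
  reproduces the drawn score to machine precision and the score
  distribution is faithful despite the absence of published
  covariances. The disorder groups without published index summaries
  (HbE trait, IDA, ID) use generic microcytic back-fill marginals,
  labelled synthetic in the preset; only their score distribution is
  meaningful.
* **component_mode** draws all components independently — no
  inter-parameter correlation is available to emulate — so emergent
  composite scores from this mode carry no correlation structure and
  are not used for score-level claims.
* The healthy controls' Hb/RBC/HCT are published per sex; the preset
  pools them as a 477:917 male:female mixture (mixture mean and
  variance).
* One transcription defect in the source summaries is corrected: the
  alpha-trait RBC row prints SD 5.08 and median 0.59 against a mean of
  5.15 x 10^6/uL, which is physiologically impossible and evidently a
  swapped cell pair; the preset stores sd = 0.59, median = 5.08 and
  carries a note.

What passing tests on these cohorts do **not** show: performance on
real analyzer data, where the three score components are correlated,
distributions are skewed in unknown ways, and pre-analytic factors
(sample age, transport) shift the CPD channels. The simulated
development AUC (~0.85, from the in-house score summaries) is also well
below the published retrospective AUC of 0.966 — the retrospective
cohort's subject-level data would be needed to reproduce that figure,
and the generator makes no attempt to fabricate it.

* **Quartiles** use linear interpolation (type-7), the numpy default;
  the whisker convention of the original box plots is unstated.
* **Oracle.** `binormal_auc` gives the closed-form
  Phi(dmu / sqrt(sd1^2 + sd2^2)) used to check ROC recovery; for the
  two carrier score summaries it evaluates to ~0.844, and seeded
  score-mode cohorts at n = 1000 per class recover it to within 0.01.

## Determinism and numerics

Every stochastic operation takes an explicit seed
(`numpy.random.default_rng`); identical spec + seed reproduce
byte-identical result tables. Result CSVs are written with 17
significant digits so a write-read cycle is bit exact. Degenerate
inputs are handled explicitly: all-identical scores give AUC 0.5 with a
warning and a median cutoff; single-record groups report an undefined
SD; an RDW draw of exactly zero in score_mode is redrawn (bounded
retries) to keep the back-fill defined.

## Problem sizes in tests

The test-suite simulations use the published group sizes (155/48
development, 119/48/15/84/44 in-house, 95 interlaboratory), n = 1000
per class for AUC-recovery checks (20 seeds), and n = 5000 per group
for moment-recovery checks — sizes at which the Monte-Carlo error is
comfortably below the asserted tolerances.

## Known limitations

* The pre-screen/scoring interaction in the published clinical flowchart
  is only depicted graphically; this package scores everyone and
  reports the pre-screen flag alongside, the one reading that loses no
  information.
* No ROC curve-comparison tests (paired DeLong), no partial AUC, no
  likelihood ratios or prevalence-adjusted predictive values.
* The CPD channels' units are analyzer-specific and treated as
  dimensionless; scores from different analyzer models are not
  comparable without re-deriving the cutoff.
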