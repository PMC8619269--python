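# thalscreen

Screening support for telling **alpha-** from **beta-thalassaemia
trait** using quantities a routine haematology analyzer already
reports: the red-cell indices of the full blood count and the
reticulocyte *cell population data* (CPD) light-scatter channels. It is
aimed at screening laboratories in high-prevalence regions that want a
cheap first-pass triage before haemoglobin analysis and DNA testing,
and at anyone evaluating composite haematology discriminants.

## The score

Beta-trait red cells show higher reticulocyte lower-median-angle light
scatter (MN-LMALS-RET), higher red-cell distribution width (RDW) and
lower mean corpuscular haemoglobin (MCH) than alpha-trait cells. The
composite discriminant combines all three:

```
S = MN-LMALS-RET × RDW − MCH
S > 1742.5   →  beta-thalassaemia trait
S ≤ 1742.5   →  alpha-thalassaemia trait
```

Around the score the package provides the full evaluation pipeline:

* `scoring` — the composite score, the microcytosis pre-screen
  (MCH < 27 pg, MCV < 80 fL, RDW > 14 %), and the classical
  discriminant indices (Mentzer, Green & King, …) for comparison;
* `roc_eval` — empirical ROC curves, Mann–Whitney AUC with DeLong or
  bootstrap confidence intervals, Youden cutoff selection, and the
  p-value/AUC parameter shortlist used in algorithm development;
* `diag_accuracy` — 2×2 contingency tables with sensitivity,
  specificity, PPV and NPV plus Wilson / exact / Wald intervals;
* `synthetic_data` — seeded synthetic cohorts parameterised by the
  published per-group summary statistics (no subject-level data is
  deposited), plus the closed-form binormal AUC oracle;
* `pipeline` / `thalscreen` CLI — `develop` and `validate`
  orchestration with reproducible, fully seeded outputs.

Calls are screening annotations: anything called beta-trait (or
otherwise flagged) should be referred for confirmatory haemoglobin
analysis; the package deliberately automates nothing downstream.

## Worked example

Score one subject from the library:

```python
from thalscreen import SubjectRecord, ab_score, classify, prescreen

r = SubjectRecord("P-001", hb=11.8, rbc=5.4, mcv=65.4, mch=20.7,
                  rdw=16.55, mn_lmals_ret=112.3)
print(ab_score(r))    # 1837.865
print(classify(ab_score(r)))  # beta_trait
print(prescreen(r))   # True
```

The score 1837.865 = 112.3 × 16.55 − 20.7 lies above the 1742.5 cutoff,
so the subject is called beta-trait and would be referred for HbA2
quantitation; `prescreen` confirms the sample would have entered
carrier work-up at all (all three microcytosis criteria fire).

From the shell, simulate a cohort with the published in-house
validation structure (five red-cell-disorder groups) and validate the
cutoff on it:

```
$ thalscreen simulate --preset validation_cohort --seed 7 --out demo
wrote 310 simulated subjects to demo/validation_cohort.csv

$ thalscreen validate demo/validation_cohort.csv --out demo_val
{
  "n_excluded": 0,
  "groups": {"alpha_trait": 119, "beta_trait": 48, "hbe_trait": 15,
             "ida": 84, "id": 44},
  "contingency": {"tp": 37, "fp": 32, "fn": 11, "tn": 87},
  "accuracy_percent": {"sensitivity": 77.08, "specificity": 73.11,
                       "ppv": 53.62, "npv": 88.78}
}
```

Here *all five* disorder groups are pushed through the alpha-vs-beta
rule, so specificity drops: the iron-deficiency-anaemia group overlaps
the beta-trait score range (visible in `demo_val/overlap.csv`, the
pairwise interquartile-overlap table). Restricted to the two carrier
groups — the question the score was built for — performance is far
higher; `run_validate` reports both views, and IDA follows a different
diagnostic pathway in practice.

Note on confidence intervals: the point estimates are the reproducible
quantities here. The originally printed CIs came from a web calculator
whose method is unstated and could not be matched by Wilson or
Clopper–Pearson recomputation; this package defaults to Wilson and
documents the choice.

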