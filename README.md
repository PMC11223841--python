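# phoenix-score

Phoenix pediatric sepsis score and criteria for tabular EHR data.

The Phoenix criteria define pediatric sepsis as life-threatening organ
dysfunction, quantified by a score over four organ systems — respiratory,
cardiovascular, coagulation, and neurologic — with age-adjusted
physiologic thresholds. Writing the Phoenix Sepsis Score as the sum of the
four sub-scores,

    total = resp (0–3) + cv (0–6) + coag (0–2) + neuro (0–2)   ∈ [0, 13]

the score-based criteria are

    sepsis        ⇔  total ≥ 2
    septic shock  ⇔  sepsis ∧ cv ≥ 1

The research-oriented Phoenix-8 extension adds endocrine, immunologic,
renal, and hepatic sub-scores (one point each), giving a 0–17 total that
never changes the sepsis or septic-shock indicators.

The package is aimed at clinical researchers scoring patient-level
extracts (one row per patient/encounter snapshot). It implements the
rubric's exact software-facing semantics:

* **Missing maps to zero.** Any absent input contributes zero points to
  every sub-score — missingness is a first-class state, never imputed.
* **Floating-point boundaries.** Lactate, MAP, and all labs are compared
  as floating-point values with the exact inequalities of the rubric
  (e.g. one cardiovascular point for `5 ≤ lactate < 11` mmol/L); nothing
  is rounded before comparison.
* **Age-adjusted cut-points.** MAP and creatinine thresholds vary over
  six age brackets from 0 to 216 months (age not adjusted for
  prematurity); every cut-point lives in one reviewable constant table
  (`phoenix_score.thresholds`).
* **Raw-EHR plumbing.** SpO₂:FiO₂ ratios are only valid when SpO₂ ≤ 97;
  MAP uses a measured value preferentially, else DBP + (SBP − DBP)/3;
  vasoactive medications are counted from six per-drug flags.

The sepsis/septic-shock columns reflect the *score-based* criteria only;
the suspected-infection component of the full clinical definition
requires longitudinal encounter data outside this package's scope.

## Worked example

A 3-year-old (36 months) presents with fever, tachycardia, and
hypotension; they are started on a norepinephrine drip, blood pressure is
67/32 mmHg, and a CBC shows platelets of 95 K/μL. Nothing else is
measured.

```python
import phoenix_score as px

snap = px.PatientSnapshot(
    age_months=36,
    vasoactive_count=px.count_vasoactives(norepinephrine=True),
    map_mmhg=px.resolve_map(None, sbp_mmhg=67, dbp_mmhg=32),
    platelets_k_ul=95,
)
print(px.phoenix(snap))
```

prints

```
PhoenixResult(respiratory=0, cardiovascular=2, coagulation=1,
              neurologic=0, total=3, sepsis=True, septic_shock=True)
```

Respiratory and neurologic score 0 (no data recorded); cardiovascular
scores 2 (one vasoactive agent, plus MAP = 32 + (67−32)/3 ≈ 43.7 mmHg,
inside the 1-point band 32 ≤ MAP < 45 for ages 24–60 months);
coagulation scores 1 (platelets < 100). The total of 3 meets the sepsis
threshold (≥ 2), and with a cardiovascular point present this is septic
shock.

## Command line

```sh
# generate a synthetic 20-row demo cohort (27 raw EHR columns)
phoenix-score fixture --n 20 --seed 42 --output cohort.csv

# score it (phoenix = 7 output columns, phoenix8 = 12)
phoenix-score score --input cohort.csv --output scores.csv --mode phoenix8
```

Column names are bound to canonical fields through a YAML/JSON mapping
file (`--mapping`); the default mapping matches the fixture layout, so
the quickstart needs no config. `--lenient` scores valid rows and writes
a sidecar error report instead of failing on the first bad cell.

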