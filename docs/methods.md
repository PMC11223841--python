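# Methods

## The scoring rubric

The package scores one patient/encounter snapshot at a time against the
Phoenix pediatric sepsis criteria. Eight organ blocks are scored
independently and summed:

| Block | Range | Inputs | Points |
|---|---|---|---|
| Respiratory | 0–3 | PaO₂:FiO₂ (PF), SpO₂:FiO₂ (SF), respiratory support, IMV | 1 pt: any support and PF < 400 or SF < 292; 2 pt: IMV and PF < 200 or SF < 220; 3 pt: IMV and PF < 100 or SF < 148 |
| Cardiovascular | 0–6 | vasoactive count, lactate, MAP, age | sum of: meds (1 pt for one agent, 2 for ≥ 2), lactate (1 pt for 5 ≤ x < 11, 2 for ≥ 11 mmol/L), age-adjusted MAP (1 pt middle band, 2 below it) |
| Coagulation | 0–2 | platelets, INR, D-dimer, fibrinogen | 1 pt each for platelets < 100 ×10³/μL, INR > 1.3, D-dimer > 2 mg/L FEU, fibrinogen < 100 mg/dL; capped at 2 |
| Neurologic | 0–2 | GCS, pupils | 2 pt for bilaterally fixed pupils (regardless of GCS); else 1 pt for GCS ≤ 10 |
| Endocrine | 0–1 | glucose | 1 pt for < 50 or > 150 mg/dL |
| Immunologic | 0–1 | ANC, ALC | 1 pt for ANC < 500 and/or ALC < 1000 cells/mm³ |
| Renal | 0–1 | creatinine, age | 1 pt at/above the age-bracket cut-point |
| Hepatic | 0–1 | bilirubin, ALT | 1 pt for bilirubin ≥ 4 mg/dL and/or ALT > 102 IU/L |

Age brackets (months, half-open) with (MAP 1-pt lower, MAP 0-pt lower;
creatinine cut): [0,1): (17, 31; 0.8), [1,12): (25, 39; 0.3),
[12,24): (31, 44; 0.4), [24,60): (32, 45; 0.6), [60,144): (36, 49; 0.7),
[144,216): (38, 52; 1.0). All cut-points are collected in
`phoenix_score/thresholds.py` so the whole rubric can be audited in one
place.

The Phoenix total is the sum of the first four blocks; sepsis is
`total ≥ 2` and septic shock is sepsis with ≥ 1 cardiovascular point.
Phoenix-8 appends the other four blocks into a 0–17 total that never
influences the flags. The emitted sepsis flag is the score-based
criterion only: operationalizing "suspected infection" needs
antimicrobial and microbiology-order events over a 24-hour encounter
window, i.e. longitudinal data this row-snapshot package deliberately
does not model.

## Missing-data and boundary semantics

Missing inputs (empty cell, `None`, NaN) are a first-class state: a
missing numeric never satisfies any inequality and a missing boolean is
treated as false, so every missing input contributes exactly zero
points. This is the rubric's own convention (absence of a test usually
means no clinical concern, and the criteria must work in low-resource
settings), not an imputation choice, and the package performs no other
imputation.

All comparisons are on raw floating-point values with the
software-facing inequalities above; lactate and MAP are *not* rounded
before comparison (a lactate of 10.95 scores 1 point, not 2). Interval
ends follow the table exactly: e.g. glucose 150.0 is normal and 150.01
abnormal; ALT 102 is normal; bilirubin 4.0 and creatinine at its
cut-point are abnormal.

Age is required (months, not adjusted for prematurity). The rubric was
developed on children under 18 years, so ages outside [0, 216) months
raise a validation error by default; `clamp_age=True` (CLI
`--clamp-age`) opts into clamping to the nearest bracket with a warning.
Silent extrapolation would misrepresent the rubric, so it is never the
default. GCS must be an integer in [3, 15] and the vasoactive count an
integer in [0, 6]; violations are validation errors naming the field and
row rather than coerced, since they indicate data-quality faults.
Bilaterally fixed pupils score 2 neurologic points regardless of GCS
value or missingness. IMV implies respiratory support: a snapshot with
`on_imv=True` is normalized to `on_respiratory_support=True` before
scoring. When both PF and SF ratios are present each tier is a
disjunction — either ratio can trigger it — and the highest applicable
tier wins.

## Derived inputs

Raw EHR extracts rarely carry the canonical scorer inputs directly, so a
normalization layer computes them:

* **SF ratio**: SpO₂/FiO₂, defined only when SpO₂ ≤ 97 % (pulse
  oximetry saturates above that, making the ratio uninformative); above
  97 the ratio is missing. A precomputed `sf_ratio` column is trusted
  as-is — if only the ratio is available the gating is assumed to have
  happened upstream, and this assumption is documented here.
* **PF ratio**: PaO₂/FiO₂; missing when either input is.
* **MAP**: a measured mean arterial pressure is used preferentially;
  otherwise DBP + (SBP − DBP)/3. Only this one hierarchy level is
  implemented: distinguishing invasive from oscillometric measurements
  would need source metadata the tabular schema does not carry, so both
  count as "measured" (a documented limitation; users wanting a deeper
  hierarchy should resolve MAP upstream).
* **Vasoactive count**: the number of distinct agents among dobutamine,
  dopamine, epinephrine, milrinone, norepinephrine, vasopressin, from
  per-drug flags; a precomputed count column is also accepted.
* **FiO₂ dialect**: canonical unit is a fraction in [0.21, 1.0]. A
  column whose values exceed 1 is interpreted as percentages and rescaled
  once (one warning per column); values below room air after rescaling
  are errors.

In the table reader, a mapped precomputed column (`pf_ratio`,
`sf_ratio`, `map_mmhg`, `vasoactive_count`) wins over raw columns for
the same quantity.

## Tabular pipeline

`read_cohort` reads RFC-4180 CSV (or TSV) with a header row, binds
columns to canonical fields through a `ColumnMapping` (flat YAML/JSON,
default matching the bundled fixture layout), parses empty cells as
missing, and validates per cell. The default policy is fail-fast with
the 1-based data-row number and column name; `lenient` scores the valid
rows and collects the rest into an error report (CLI: a
`*.errors.csv` sidecar), because silently part-scoring a clinical
dataset is worse than stopping. `score_table` applies the vectorized
scorers column-wise — scoring a table is exactly element-wise scoring of
its rows, which the test suite asserts — and emits integer columns with
0/1 flags (friendlier to downstream statistics than booleans):
7 columns for Phoenix, 12 for Phoenix-8, preserving row order and an
optional identifier column.

## Synthetic cohort generator

`generate_cohort` emulates the *structure* of a pediatric ICU extract:
20 observations × 27 variables by default (a row id, age, SpO₂, FiO₂,
PaO₂, a ventilation flag, six vasoactive flags, SBP/DBP, lactate, four
coagulation labs, GCS, pupils, glucose, ANC, ALC, creatinine, bilirubin,
ALT). Values are drawn from plausible clinical ranges spanning every
scoring tier; ages are stratified across all six brackets; per-field
missingness uses realistic defaults (blood gases and D-dimer are ordered
far less often than vitals) with a uniform override. A few rows are
pinned deterministically so the default cohort always realizes every MAP
tier and at least one nonzero sub-score per organ block, and every
maskable field has at least one missing row. Identical specs give
byte-identical CSVs; all randomness in the package is confined to this
module. The 27-column realization folds "any respiratory support" into
the single ventilation flag and omits a pre-measured MAP column (MAP is
estimated from SBP/DBP), which keeps the variable count faithful while
still exercising the support-implication and MAP-estimation code paths;
the measured-MAP preference is covered by unit tests instead.

What the generator does **not** emulate: longitudinal trajectories,
correlated organ failure (fields are sampled independently), measurement
artifacts, or real missingness mechanisms (missingness is completely at
random). Passing tests on this cohort therefore demonstrate correctness
of the scoring semantics, not calibration or validity on real EHR data.

The worked-example row (36 months, norepinephrine, BP 67/32, platelets
95) is the only value-exact fixture; it is generated from its raw inputs
at call time, never stored.

## Verification strategy and numerical choices

Correctness rests on a dual route: every scorer is compared, element for
element, against an independently coded naive per-row scorer (plain
if/else chains with literal thresholds, in the test suite, sharing no
code with the package) on a deterministic boundary grid of ~55,000 rows.
The grid probes each threshold at, just below, and just above its
cut-point (ε = 0.01 — well above double-precision noise, far below
clinical resolution), in every age bracket, and crosses representative
per-block inputs so that every combination of sub-score levels — hence
every total, the sepsis/shock activation edges, and the 17-point
maximum — is realized. The grid's row count is asserted against a
closed-form product of its component sizes. Hypothesis-based property
suites (derandomized) add: sub-score ranges, additivity, flag
consistency, missingness monotonicity (nulling any field never raises
any score), clinical monotonicity (worsening any input in its risk
direction never lowers its sub-score), Phoenix/Phoenix-8 agreement, and
table-vs-row scoring equivalence including the empty table. These sizes
keep the full suite around ten seconds on one CPU while still
enumerating every decision boundary.

## Known limitations

* Score-based flags only; suspected infection is not evaluated.
* One MAP hierarchy level; no medication-dose parsing; no unit inference
  beyond the FiO₂ percent/fraction rule.
* Row-snapshot model: no time-windowing or worst-value aggregation over
  an encounter.
* No mortality prediction or any statistical modelling on top of the
  score.
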