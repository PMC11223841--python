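"""Synthetic patient tables for demonstration and testing.

Three generators, all deterministic:

* :func:`generate_cohort` — a seeded synthetic cohort in the 27-column raw
  EHR layout (one ventilation flag, six vasoactive flags, SBP/DBP rather
  than a precomputed MAP), with per-field missingness and ages stratified
  across all six brackets. It emulates the *structure* of real pediatric
  ICU extracts — variable set, plausible ranges, missing cells — not any
  real patients.
* :func:`worked_example_row` — the canonical single-patient example: a
  3-year-old on a norepinephrine drip, blood pressure 67/32 mmHg, platelet
  count 95 K/uL, everything else unmeasured.
* :func:`boundary_grid` — a deterministic grid probing every scoring
  threshold at, just below, and just above its cut-point, in every age
  bracket, crossed with representative combinations of all eight organ
  blocks. Used by the oracle-equivalence and definitional-threshold suites.

Random number use is confined to this module; scoring is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from itertools import product
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import thresholds as T
from .derived import resolve_map
from .snapshot import PatientSnapshot

__all__ = [
    "FixtureSpec",
    "FIXTURE_COLUMNS",
    "generate_cohort",
    "worked_example_row",
    "worked_example_frame",
    "boundary_grid",
    "boundary_grid_expected_rows",
]

#: Raw-table layout: 27 variables per observation.
FIXTURE_COLUMNS = (
    "pid",
    "age",
    "spo2",
    "fio2",
    "pao2",
    "vent",
    "dobutamine",
    "dopamine",
    "epinephrine",
    "milrinone",
    "norepinephrine",
    "vasopressin",
    "sbp",
    "dbp",
    "lactate",
    "platelets",
    "inr",
    "d_dimer",
    "fibrinogen",
    "gcs",
    "fixed_pupils",
    "glucose",
    "anc",
    "alc",
    "creatinine",
    "bilirubin",
    "alt",
)

_BOOL_COLUMNS = (
    "vent",
    "dobutamine",
    "dopamine",
    "epinephrine",
    "milrinone",
    "norepinephrine",
    "vasopressin",
    "fixed_pupils",
)

#: Fraction of rows left unmeasured per field; loosely modelled on how
#: often each test is actually ordered in pediatric ICU care (blood gases
#: and coagulation panels are ordered far less often than vitals).
DEFAULT_MISSINGNESS: Dict[str, float] = {
    "spo2": 0.15,
    "fio2": 0.20,
    "pao2": 0.60,
    "vent": 0.10,
    "dobutamine": 0.10,
    "dopamine": 0.10,
    "epinephrine": 0.10,
    "milrinone": 0.10,
    "norepinephrine": 0.10,
    "vasopressin": 0.10,
    "sbp": 0.10,
    "dbp": 0.10,
    "lactate": 0.35,
    "platelets": 0.25,
    "inr": 0.40,
    "d_dimer": 0.50,
    "fibrinogen": 0.50,
    "gcs": 0.25,
    "fixed_pupils": 0.25,
    "glucose": 0.30,
    "anc": 0.40,
    "alc": 0.40,
    "creatinine": 0.25,
    "bilirubin": 0.35,
    "alt": 0.35,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic cohort.

    ``missingness`` overrides the per-field defaults; a single float
    applies one rate to every maskable field (``pid`` and ``age`` are
    never missing).
    """

    n_rows: int = 20
    seed: int = 42
    missingness: Optional[float] = None
    missingness_by_field: Dict[str, float] = dc_field(default_factory=dict)

    def rates(self) -> Dict[str, float]:
        base = dict(DEFAULT_MISSINGNESS)
        if self.missingness is not None:
            if not 0.0 <= self.missingness <= 1.0:
                raise ValueError("missingness must be in [0, 1]")
            base = {k: self.missingness for k in base}
        base.update(self.missingness_by_field)
        return base


def generate_cohort(spec: Optional[FixtureSpec] = None, **kwargs) -> pd.DataFrame:
    """Generate the synthetic raw cohort table (``n_rows`` x 27).

    Identical specs produce identical tables. Ages are stratified so every
    age bracket appears (for n >= 6), the first three rows realize each
    MAP scoring tier, and a handful of rows are pinned to guarantee at
    least one nonzero sub-score per organ block (for n >= 11).
    """
    if spec is None:
        spec = FixtureSpec(**kwargs)
    elif kwargs:
        raise TypeError("pass either a FixtureSpec or keyword arguments")
    if spec.n_rows < 0:
        raise ValueError("n_rows must be non-negative")
    n = spec.n_rows
    rng = np.random.default_rng(spec.seed)
    rates = spec.rates()

    brackets = [T.AGE_BRACKETS[i % len(T.AGE_BRACKETS)] for i in range(n)]
    age = np.array(
        [
            rng.uniform(b.lo_months + 0.2, b.hi_months - 0.2)
            for b in brackets
        ]
    )

    cols: Dict[str, np.ndarray] = {
        "age": np.round(age, 1),
        "spo2": np.round(rng.uniform(85.0, 100.0, n), 1),
        "fio2": np.round(rng.uniform(0.21, 1.0, n), 2),
        "pao2": np.round(rng.uniform(40.0, 500.0, n), 1),
        "vent": rng.binomial(1, 0.3, n).astype(float),
        "lactate": np.round(rng.uniform(0.5, 13.0, n), 1),
        "platelets": np.round(rng.uniform(20.0, 450.0, n), 0),
        "inr": np.round(rng.uniform(0.9, 2.5, n), 2),
        "d_dimer": np.round(rng.uniform(0.1, 6.0, n), 2),
        "fibrinogen": np.round(rng.uniform(60.0, 400.0, n), 0),
        "gcs": rng.integers(3, 16, n).astype(float),
        "fixed_pupils": rng.binomial(1, 0.05, n).astype(float),
        "glucose": np.round(rng.uniform(30.0, 250.0, n), 0),
        "anc": np.round(rng.uniform(100.0, 15000.0, n), 0),
        "alc": np.round(rng.uniform(200.0, 5000.0, n), 0),
        "creatinine": np.round(rng.uniform(0.1, 2.0, n), 2),
        "bilirubin": np.round(rng.uniform(0.2, 8.0, n), 1),
        "alt": np.round(rng.uniform(10.0, 300.0, n), 0),
    }
    for agent in T.VASOACTIVE_AGENTS:
        cols[agent] = rng.binomial(1, 0.15, n).astype(float)

    # blood pressures from a target MAP inside the row's bracket band
    # (MAP = DBP + (SBP - DBP)/3, so DBP = MAP - 5, SBP = MAP + 10)
    map_target = np.array(
        [
            rng.uniform(0.7 * b.map_1pt_lower, 1.3 * b.map_0pt_lower)
            for b in brackets
        ]
    )
    # first three rows pin each MAP tier: 2 points, 1 point, 0 points
    for i, tier in zip(range(min(n, 3)), (2, 1, 0)):
        b = brackets[i]
        map_target[i] = {
            2: b.map_1pt_lower - 5.0,
            1: (b.map_1pt_lower + b.map_0pt_lower) / 2.0,
            0: b.map_0pt_lower + 10.0,
        }[tier]
    cols["dbp"] = np.round(np.maximum(map_target - 5.0, 5.0), 1)
    cols["sbp"] = np.round(map_target + 10.0, 1)

    # missingness masks
    masked: Dict[str, np.ndarray] = {}
    maskable = [c for c in FIXTURE_COLUMNS if c not in ("pid", "age")]
    for c in maskable:
        masked[c] = rng.random(n) < rates.get(c, 0.0)
    # keep SBP/DBP jointly present or jointly missing
    masked["dbp"] = masked["sbp"] = masked["sbp"] | masked["dbp"]

    # pinned rows guaranteeing nonzero coverage of every organ block
    pins: List[tuple] = [
        (3, {"vent": 1.0, "pao2": 150.0, "fio2": 1.0}),  # respiratory 2
        (4, {"norepinephrine": 1.0}),  # vasoactive point
        (5, {"platelets": 80.0}),  # coagulation
        (6, {"gcs": 7.0}),  # neurologic
        (7, {"glucose": 40.0}),  # endocrine
        (8, {"anc": 300.0}),  # immunologic
        (9, {"creatinine": brackets[9].creatinine_1pt_lower + 0.5 if n > 9 else 1.0}),
        (10, {"bilirubin": 5.0}),  # hepatic
    ]
    for row, values in pins:
        if row >= n:
            continue
        for c, v in values.items():
            cols[c][row] = v
            masked[c][row] = False
    for i in range(min(n, 3)):  # MAP tier rows keep their pressures
        masked["sbp"][i] = masked["dbp"][i] = False

    # every maskable field gets at least one missing row
    for j, c in enumerate(maskable):
        if n > 0 and not masked[c].any():
            masked[c][(7 * j + 3) % n] = True

    data: Dict[str, list] = {"pid": [f"p{i + 1:03d}" for i in range(n)]}
    data["age"] = list(cols["age"])
    for c in FIXTURE_COLUMNS[2:]:
        vals = []
        for i in range(n):
            if masked[c][i]:
                vals.append(None)
            elif c in _BOOL_COLUMNS or c == "gcs":
                vals.append(int(cols[c][i]))
            else:
                vals.append(float(cols[c][i]))
        data[c] = vals
    frame = pd.DataFrame(data, columns=list(FIXTURE_COLUMNS))
    for c in _BOOL_COLUMNS + ("gcs",):
        frame[c] = frame[c].astype("Int64")  # 0/1 without decimal points
    return frame


def worked_example_row() -> PatientSnapshot:
    """The canonical single-patient example as a validated snapshot.

    A 3-year-old (36 months) with fever and hypotension, started on a
    norepinephrine drip; blood pressure 67/32 mmHg (MAP estimated from
    SBP/DBP), platelets 95 K/uL; nothing else measured.
    """
    return PatientSnapshot(
        age_months=36.0,
        vasoactive_count=1,
        map_mmhg=resolve_map(None, 67.0, 32.0),
        platelets_k_ul=95.0,
    )


def worked_example_frame() -> pd.DataFrame:
    """The same example as a one-row raw table in the fixture layout."""
    row = {c: None for c in FIXTURE_COLUMNS}
    row.update(
        pid="example",
        age=36.0,
        norepinephrine=1,
        sbp=67.0,
        dbp=32.0,
        platelets=95.0,
    )
    return pd.DataFrame([row], columns=list(FIXTURE_COLUMNS))


# ------------------------------------------------------------ boundary grid

_EPS = 0.01  # well above double-precision noise, below clinical resolution


def _around(x: float, eps: float) -> List[float]:
    return [x - eps, x, x + eps]


def _grid_components(eps: float) -> Dict[str, list]:
    nan = np.nan
    comp: Dict[str, list] = {}

    # bracket sweep: MAP and creatinine boundaries in every age bracket
    bracket_rows = []
    for b in T.AGE_BRACKETS:
        ages = [b.lo_months, (b.lo_months + b.hi_months) / 2.0,
                b.hi_months - eps]
        maps = (_around(b.map_1pt_lower, eps) + _around(b.map_0pt_lower, eps)
                + [nan])
        creats = [b.creatinine_1pt_lower - eps, b.creatinine_1pt_lower, nan]
        for a, m, c in product(ages, maps, creats):
            bracket_rows.append((a, m, c))
    comp["bracket_rows"] = bracket_rows

    # per-block sweeps at a fixed mid-range age
    comp["resp_pf"] = [nan] + sum(
        (_around(v, eps) for v in (T.PF_3PT_UPPER, T.PF_2PT_UPPER,
                                   T.PF_1PT_UPPER)), [])
    comp["resp_sf"] = [nan] + sum(
        (_around(v, eps) for v in (T.SF_3PT_UPPER, T.SF_2PT_UPPER,
                                   T.SF_1PT_UPPER)), [])
    comp["resp_flags"] = [(0, 0), (0, 1), (1, 0), (1, 1)]
    comp["cv_count"] = [nan, 0, 1, 2, 6]
    comp["cv_lactate"] = [nan] + _around(T.LACTATE_1PT_LOWER, eps) + _around(
        T.LACTATE_2PT_LOWER, eps)
    b36 = T.AGE_BRACKETS[3]  # the 24-60 month bracket
    comp["cv_map"] = [nan] + _around(b36.map_1pt_lower, eps) + _around(
        b36.map_0pt_lower, eps)
    comp["coag_platelets"] = [nan] + _around(T.PLATELETS_1PT_UPPER, eps)
    comp["coag_inr"] = [nan] + _around(T.INR_1PT_ABOVE, eps)
    comp["coag_ddimer"] = [nan] + _around(T.DDIMER_1PT_ABOVE, eps)
    comp["coag_fibrinogen"] = [nan] + _around(T.FIBRINOGEN_1PT_UPPER, eps)
    comp["neuro_gcs"] = [nan, 3, 10, 11, 15]
    comp["neuro_pupils"] = [0, 1]
    comp["endo_glucose"] = [nan] + _around(T.GLUCOSE_LOW, eps) + _around(
        T.GLUCOSE_HIGH, eps)
    comp["immu_anc"] = [nan] + _around(T.ANC_1PT_UPPER, eps)
    comp["immu_alc"] = [nan] + _around(T.ALC_1PT_UPPER, eps)
    comp["hep_bili"] = [nan] + _around(T.BILIRUBIN_1PT_LOWER, eps)
    comp["hep_alt"] = [nan] + _around(T.ALT_1PT_ABOVE, eps)

    # representative combinations realizing each sub-score level, used for
    # the full cross-block product (at age 36 months)
    comp["x_resp"] = [  # (pf, sf, imv, support) -> 0,1,2,3,3
        (nan, nan, 0, 0),
        (T.PF_1PT_UPPER - eps, nan, 0, 1),
        (nan, T.SF_2PT_UPPER - eps, 1, 0),
        (T.PF_3PT_UPPER - eps, nan, 1, 1),
        (nan, T.SF_3PT_UPPER - eps, 1, 1),
    ]
    comp["x_cv"] = [
        (c, l, m)
        for c in (0, 1, 2)
        for l in (nan, T.LACTATE_1PT_LOWER - eps, T.LACTATE_1PT_LOWER,
                  T.LACTATE_2PT_LOWER - eps, T.LACTATE_2PT_LOWER)
        for m in (nan, b36.map_0pt_lower, b36.map_0pt_lower - eps,
                  b36.map_1pt_lower, b36.map_1pt_lower - eps)
    ]
    comp["x_coag"] = [  # (platelets, inr) -> 0, 1, 2
        (nan, nan),
        (T.PLATELETS_1PT_UPPER - eps, nan),
        (T.PLATELETS_1PT_UPPER - eps, T.INR_1PT_ABOVE + eps),
    ]
    comp["x_neuro"] = [(nan, 0), (10, 0), (nan, 1)]
    comp["x_glucose"] = [nan, T.GLUCOSE_LOW - eps]
    comp["x_anc"] = [nan, T.ANC_1PT_UPPER - eps]
    comp["x_creatinine"] = [nan, b36.creatinine_1pt_lower + eps]
    comp["x_bilirubin"] = [nan, T.BILIRUBIN_1PT_LOWER + eps]
    return comp


def boundary_grid_expected_rows(eps: float = _EPS) -> int:
    """Closed-form row count of :func:`boundary_grid`, computed from the
    sizes of its component value lists."""
    c = _grid_components(eps)
    n_bracket = len(c["bracket_rows"])
    n_block = (
        len(c["resp_pf"]) * len(c["resp_sf"]) * len(c["resp_flags"])
        + len(c["cv_count"]) * len(c["cv_lactate"]) * len(c["cv_map"])
        + len(c["coag_platelets"]) * len(c["coag_inr"])
        * len(c["coag_ddimer"]) * len(c["coag_fibrinogen"])
        + len(c["neuro_gcs"]) * len(c["neuro_pupils"])
        + len(c["endo_glucose"])
        + len(c["immu_anc"]) * len(c["immu_alc"])
        + len(c["hep_bili"]) * len(c["hep_alt"])
    )
    n_cross = (
        len(c["x_resp"]) * len(c["x_cv"]) * len(c["x_coag"])
        * len(c["x_neuro"]) * len(c["x_glucose"]) * len(c["x_anc"])
        * len(c["x_creatinine"]) * len(c["x_bilirubin"])
    )
    return n_bracket + n_block + n_cross


_GRID_COLUMNS = (
    "age_months",
    "pf_ratio",
    "sf_ratio",
    "on_imv",
    "on_respiratory_support",
    "vasoactive_count",
    "lactate_mmol_l",
    "map_mmhg",
    "platelets_k_ul",
    "inr",
    "d_dimer_mg_l",
    "fibrinogen_mg_dl",
    "gcs",
    "fixed_pupils_bilateral",
    "glucose_mg_dl",
    "anc_cells_mm3",
    "alc_cells_mm3",
    "creatinine_mg_dl",
    "bilirubin_mg_dl",
    "alt_iu_l",
)

_MID_AGE = 36.0  # months; lies in the 24-60 bracket


def boundary_grid(eps: float = _EPS) -> pd.DataFrame:
    """Deterministic threshold-probing grid in canonical snapshot columns.

    Three sections: (1) MAP/creatinine boundaries in every age bracket,
    (2) each scalar threshold at cut-point and cut-point +/- ``eps`` with
    all other blocks missing, (3) the full cross product of representative
    per-block input combinations, realizing every combination of
    sub-score levels (and hence every total, including the maxima).
    Missing numeric cells are NaN; boolean columns are 0/1.
    """
    c = _grid_components(eps)
    rows: List[dict] = []

    def base() -> dict:
        r = {col: np.nan for col in _GRID_COLUMNS}
        r["age_months"] = _MID_AGE
        r["on_imv"] = 0
        r["on_respiratory_support"] = 0
        r["fixed_pupils_bilateral"] = 0
        return r

    for a, m, cre in c["bracket_rows"]:
        r = base()
        r.update(age_months=a, map_mmhg=m, creatinine_mg_dl=cre)
        rows.append(r)

    for pf, sf, (imv, sup) in product(
        c["resp_pf"], c["resp_sf"], c["resp_flags"]
    ):
        r = base()
        r.update(pf_ratio=pf, sf_ratio=sf, on_imv=imv,
                 on_respiratory_support=sup)
        rows.append(r)
    for cnt, lac, m in product(c["cv_count"], c["cv_lactate"], c["cv_map"]):
        r = base()
        r.update(vasoactive_count=cnt, lactate_mmol_l=lac, map_mmhg=m)
        rows.append(r)
    for plt, inr, dd, fib in product(
        c["coag_platelets"], c["coag_inr"], c["coag_ddimer"],
        c["coag_fibrinogen"]
    ):
        r = base()
        r.update(platelets_k_ul=plt, inr=inr, d_dimer_mg_l=dd,
                 fibrinogen_mg_dl=fib)
        rows.append(r)
    for g, pup in product(c["neuro_gcs"], c["neuro_pupils"]):
        r = base()
        r.update(gcs=g, fixed_pupils_bilateral=pup)
        rows.append(r)
    for glu in c["endo_glucose"]:
        r = base()
        r.update(glucose_mg_dl=glu)
        rows.append(r)
    for anc, alc in product(c["immu_anc"], c["immu_alc"]):
        r = base()
        r.update(anc_cells_mm3=anc, alc_cells_mm3=alc)
        rows.append(r)
    for bil, alt in product(c["hep_bili"], c["hep_alt"]):
        r = base()
        r.update(bilirubin_mg_dl=bil, alt_iu_l=alt)
        rows.append(r)

    for resp, cv, coag, neuro, glu, anc, cre, bil in product(
        c["x_resp"], c["x_cv"], c["x_coag"], c["x_neuro"],
        c["x_glucose"], c["x_anc"], c["x_creatinine"], c["x_bilirubin"]
    ):
        r = base()
        r.update(
            pf_ratio=resp[0], sf_ratio=resp[1], on_imv=resp[2],
            on_respiratory_support=resp[3],
            vasoactive_count=cv[0], lactate_mmol_l=cv[1], map_mmhg=cv[2],
            platelets_k_ul=coag[0], inr=coag[1],
            gcs=neuro[0], fixed_pupils_bilateral=neuro[1],
            glucose_mg_dl=glu, anc_cells_mm3=anc, creatinine_mg_dl=cre,
            bilirubin_mg_dl=bil,
        )
        rows.append(r)

    grid = pd.DataFrame(rows, columns=list(_GRID_COLUMNS))
    expected = boundary_grid_expected_rows(eps)
    assert len(grid) == expected, (len(grid), expected)
    return grid
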