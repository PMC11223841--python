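"""Organ-dysfunction scorers for the Phoenix pediatric sepsis criteria.

Eight sub-score functions (respiratory, cardiovascular, coagulation,
neurologic, endocrine, immunologic, renal, hepatic), the 4-system
``phoenix`` total with sepsis / septic-shock indicators, and the 8-system
``phoenix8`` extension.

All scorers accept scalars or 1-D array-likes (lists, numpy arrays, pandas
Series) and broadcast length-1 inputs against longer ones. Missing values
(``None`` or NaN) are first-class: a missing input never satisfies any
inequality and therefore contributes zero points. Missing booleans are
treated as false. Given only scalars, a scorer returns a plain ``int``;
given any array input it returns an ``int64`` numpy array.

Age is required wherever an age-adjusted cut-point applies (cardiovascular,
renal, and the two totals). The criteria were developed on children under
18 years; ages outside ``[0, 216)`` months raise a validation error unless
``clamp_age=True``, which clamps to the nearest bracket and warns.
"""

from __future__ import annotations

import warnings
from typing import Any, Optional, Tuple

import numpy as np

from . import _coerce as _c
from . import thresholds as T
from .errors import PhoenixValidationError
from .snapshot import PatientSnapshot, PhoenixResult, Phoenix8Result

__all__ = [
    "score_respiratory",
    "score_cardiovascular",
    "score_coagulation",
    "score_neurologic",
    "score_endocrine",
    "score_immunologic",
    "score_renal",
    "score_hepatic",
    "phoenix",
    "phoenix8",
]


# ---------------------------------------------------------------- coercion

_is_scalar = _c.is_scalar
_float_col = _c.float_col
_bool_col = _c.bool_col
_broadcast = _c.broadcast


def _ret(pts, scalar: bool):
    pts = pts.astype(np.int64)
    return int(pts[0]) if scalar else pts


def _count_col(x: Any, field: str = "vasoactive_count") -> Tuple[np.ndarray, bool]:
    """Vasoactive-agent count: integer 0-6 when present, NaN when missing."""
    arr, scalar = _float_col(x, field)
    finite = np.isfinite(arr)
    bad = finite & ((arr > 6) | (arr != np.floor(arr)))
    if bad.any():
        raise PhoenixValidationError(
            field,
            "must be an integer between 0 and 6",
            rows=None if scalar else list(np.flatnonzero(bad)),
        )
    return arr, scalar


def _age_col(
    age_months: Any, clamp_age: bool = False
) -> Tuple[np.ndarray, bool]:
    arr, scalar = _float_col(age_months, "age_months", check_negative=False)
    missing = ~np.isfinite(arr)
    if missing.any():
        raise PhoenixValidationError(
            "age_months",
            "age is required for age-adjusted scoring",
            rows=None if scalar else list(np.flatnonzero(missing)),
        )
    out_of_range = (arr < 0) | (arr >= T.MAX_AGE_MONTHS)
    if out_of_range.any():
        if not clamp_age:
            raise PhoenixValidationError(
                "age_months",
                f"age must be in [0, {T.MAX_AGE_MONTHS:g}) months (criteria "
                "apply to children under 18 years); pass clamp_age=True to "
                "score with the nearest bracket",
                rows=None if scalar else list(np.flatnonzero(out_of_range)),
            )
        warnings.warn(
            f"{int(out_of_range.sum())} age value(s) outside "
            f"[0, {T.MAX_AGE_MONTHS:g}) months clamped to the nearest bracket",
            stacklevel=3,
        )
        arr = np.clip(arr, 0.0, np.nextafter(T.MAX_AGE_MONTHS, 0.0))
    return arr, scalar


# ---------------------------------------------------------------- scorers


def score_respiratory(
    pf_ratio: Any = None,
    sf_ratio: Any = None,
    on_imv: Any = None,
    on_respiratory_support: Any = None,
):
    """Respiratory sub-score, 0-3 points.

    3 points on IMV with PF < 100 or SF < 148; 2 points on IMV with
    PF < 200 or SF < 220; 1 point on any respiratory support with
    PF < 400 or SF < 292. IMV implies respiratory support. The SF ratio
    must already be validity-gated upstream (missing unless SpO2 <= 97).
    """
    pf, s1 = _float_col(pf_ratio, "pf_ratio")
    sf, s2 = _float_col(sf_ratio, "sf_ratio")
    imv, s3 = _bool_col(on_imv, "on_imv")
    sup, s4 = _bool_col(on_respiratory_support, "on_respiratory_support")
    pf, sf, imv, sup = _broadcast(pf, sf, imv, sup)
    sup = sup | imv  # IMV is a form of respiratory support

    tier3 = imv & ((pf < T.PF_3PT_UPPER) | (sf < T.SF_3PT_UPPER))
    tier2 = imv & ((pf < T.PF_2PT_UPPER) | (sf < T.SF_2PT_UPPER))
    tier1 = sup & ((pf < T.PF_1PT_UPPER) | (sf < T.SF_1PT_UPPER))
    pts = np.select([tier3, tier2, tier1], [3, 2, 1], default=0)
    return _ret(pts, s1 and s2 and s3 and s4)


def score_cardiovascular(
    vasoactive_count: Any = None,
    lactate_mmol_l: Any = None,
    map_mmhg: Any = None,
    age_months: Any = None,
    *,
    clamp_age: bool = False,
):
    """Cardiovascular sub-score, 0-6 points: medications + lactate + MAP.

    Medications: 1 point for one vasoactive agent, 2 for two or more.
    Lactate (mmol/L): 1 point for 5 <= lactate < 11, 2 at/above 11.
    MAP (mmHg): age-bracket cut-points; 1 point in the middle band,
    2 below it. Lactate and MAP are compared as floating-point values.
    """
    cnt, s1 = _count_col(vasoactive_count)
    lact, s2 = _float_col(lactate_mmol_l, "lactate_mmol_l")
    mp, s3 = _float_col(map_mmhg, "map_mmhg")
    age, s4 = _age_col(age_months, clamp_age)
    cnt, lact, mp, age = _broadcast(cnt, lact, mp, age)

    med_pts = np.select([cnt >= 2, cnt == 1], [2, 1], default=0)
    lact_pts = np.select(
        [lact >= T.LACTATE_2PT_LOWER, lact >= T.LACTATE_1PT_LOWER],
        [2, 1],
        default=0,
    )
    idx = T.bracket_index(age)
    lo1 = T.MAP_1PT_LOWER[idx]
    lo0 = T.MAP_0PT_LOWER[idx]
    map_pts = np.select([mp < lo1, mp < lo0], [2, 1], default=0)
    return _ret(med_pts + lact_pts + map_pts, s1 and s2 and s3 and s4)


def score_coagulation(
    platelets_k_ul: Any = None,
    inr: Any = None,
    d_dimer_mg_l: Any = None,
    fibrinogen_mg_dl: Any = None,
):
    """Coagulation sub-score: 1 point per abnormal lab, capped at 2.

    Abnormal: platelets < 100 (10^3/uL), INR > 1.3, D-dimer > 2 (mg/L FEU),
    fibrinogen < 100 (mg/dL).
    """
    plt, s1 = _float_col(platelets_k_ul, "platelets_k_ul")
    inr_, s2 = _float_col(inr, "inr")
    dd, s3 = _float_col(d_dimer_mg_l, "d_dimer_mg_l")
    fib, s4 = _float_col(fibrinogen_mg_dl, "fibrinogen_mg_dl")
    plt, inr_, dd, fib = _broadcast(plt, inr_, dd, fib)

    pts = (
        (plt < T.PLATELETS_1PT_UPPER).astype(np.int64)
        + (inr_ > T.INR_1PT_ABOVE)
        + (dd > T.DDIMER_1PT_ABOVE)
        + (fib < T.FIBRINOGEN_1PT_UPPER)
    )
    return _ret(np.minimum(pts, 2), s1 and s2 and s3 and s4)


def score_neurologic(gcs: Any = None, fixed_pupils_bilateral: Any = None):
    """Neurologic sub-score: 2 points for bilaterally fixed pupils
    (regardless of GCS), else 1 point for GCS <= 10, else 0."""
    g, s1 = _float_col(gcs, "gcs")
    finite = np.isfinite(g)
    bad = finite & ((g < 3) | (g > 15) | (g != np.floor(g)))
    if bad.any():
        raise PhoenixValidationError(
            "gcs",
            "must be an integer between 3 and 15",
            rows=None if s1 else list(np.flatnonzero(bad)),
        )
    pupils, s2 = _bool_col(fixed_pupils_bilateral, "fixed_pupils_bilateral")
    g, pupils = _broadcast(g, pupils)
    pts = np.select([pupils, g <= T.GCS_1PT_MAX], [2, 1], default=0)
    return _ret(pts, s1 and s2)


def score_endocrine(glucose_mg_dl: Any = None):
    """Endocrine sub-score: 1 point for blood glucose < 50 or > 150 mg/dL."""
    glu, scalar = _float_col(glucose_mg_dl, "glucose_mg_dl")
    pts = ((glu < T.GLUCOSE_LOW) | (glu > T.GLUCOSE_HIGH)).astype(np.int64)
    return _ret(pts, scalar)


def score_immunologic(anc_cells_mm3: Any = None, alc_cells_mm3: Any = None):
    """Immunologic sub-score: 1 point for ANC < 500 and/or ALC < 1000
    cells/mm^3 (single point even when both are abnormal)."""
    anc, s1 = _float_col(anc_cells_mm3, "anc_cells_mm3")
    alc, s2 = _float_col(alc_cells_mm3, "alc_cells_mm3")
    anc, alc = _broadcast(anc, alc)
    pts = ((anc < T.ANC_1PT_UPPER) | (alc < T.ALC_1PT_UPPER)).astype(np.int64)
    return _ret(pts, s1 and s2)


def score_renal(
    creatinine_mg_dl: Any = None,
    age_months: Any = None,
    *,
    clamp_age: bool = False,
):
    """Renal sub-score: 1 point for creatinine at/above the age-bracket
    cut-point (mg/dL)."""
    cre, s1 = _float_col(creatinine_mg_dl, "creatinine_mg_dl")
    age, s2 = _age_col(age_months, clamp_age)
    cre, age = _broadcast(cre, age)
    cut = T.CREATININE_1PT_LOWER[T.bracket_index(age)]
    return _ret((cre >= cut).astype(np.int64), s1 and s2)


def score_hepatic(bilirubin_mg_dl: Any = None, alt_iu_l: Any = None):
    """Hepatic sub-score: 1 point for total bilirubin >= 4 mg/dL and/or
    ALT > 102 IU/L (single point)."""
    bili, s1 = _float_col(bilirubin_mg_dl, "bilirubin_mg_dl")
    alt, s2 = _float_col(alt_iu_l, "alt_iu_l")
    bili, alt = _broadcast(bili, alt)
    pts = ((bili >= T.BILIRUBIN_1PT_LOWER) | (alt > T.ALT_1PT_ABOVE)).astype(
        np.int64
    )
    return _ret(pts, s1 and s2)


# ----------------------------------------------------------------- totals


def phoenix(
    snapshot: PatientSnapshot, *, clamp_age: bool = False
) -> PhoenixResult:
    """Score one patient snapshot with the 4-system Phoenix criteria.

    Returns the four sub-scores, their total, and the score-based sepsis
    (total >= 2) and septic-shock (sepsis with >= 1 cardiovascular point)
    indicators. The indicators reflect only the scoring rubric; the
    suspected-infection component of the full clinical definition is not
    evaluated here.
    """
    resp = score_respiratory(
        snapshot.pf_ratio,
        snapshot.sf_ratio,
        snapshot.on_imv,
        snapshot.on_respiratory_support,
    )
    cv = score_cardiovascular(
        snapshot.vasoactive_count,
        snapshot.lactate_mmol_l,
        snapshot.map_mmhg,
        snapshot.age_months,
        clamp_age=clamp_age,
    )
    coag = score_coagulation(
        snapshot.platelets_k_ul,
        snapshot.inr,
        snapshot.d_dimer_mg_l,
        snapshot.fibrinogen_mg_dl,
    )
    neuro = score_neurologic(snapshot.gcs, snapshot.fixed_pupils_bilateral)
    total = resp + cv + coag + neuro
    sepsis = total >= 2
    return PhoenixResult(
        respiratory=resp,
        cardiovascular=cv,
        coagulation=coag,
        neurologic=neuro,
        total=total,
        sepsis=sepsis,
        septic_shock=sepsis and cv >= 1,
    )


def phoenix8(
    snapshot: PatientSnapshot, *, clamp_age: bool = False
) -> Phoenix8Result:
    """Score one patient snapshot with the 8-system Phoenix-8 extension.

    The four core sub-scores, the total, and both indicators are identical
    to :func:`phoenix`; the endocrine, immunologic, renal, and hepatic
    sub-scores extend the total to ``total8`` (0-17) but never influence
    the sepsis or septic-shock flags.
    """
    base = phoenix(snapshot, clamp_age=clamp_age)
    endo = score_endocrine(snapshot.glucose_mg_dl)
    immu = score_immunologic(snapshot.anc_cells_mm3, snapshot.alc_cells_mm3)
    renal = score_renal(
        snapshot.creatinine_mg_dl, snapshot.age_months, clamp_age=clamp_age
    )
    hep = score_hepatic(snapshot.bilirubin_mg_dl, snapshot.alt_iu_l)
    return Phoenix8Result(
        respiratory=base.respiratory,
        cardiovascular=base.cardiovascular,
        coagulation=base.coagulation,
        neurologic=base.neurologic,
        total=base.total,
        sepsis=base.sepsis,
        septic_shock=base.septic_shock,
        endocrine=endo,
        immunologic=immu,
        renal=renal,
        hepatic=hep,
        total8=base.total + endo + immu + renal + hep,
    )
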