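"""Independent naive per-row scorer used as a test oracle.

Deliberately written as plain literal-threshold if/else chains over one
row at a time, sharing no code or constant tables with the package. Any
disagreement between this and the vectorized implementation on the
boundary grid is a bug in one of them.
"""

import math


def _missing(x):
    if x is None:
        return True
    try:
        return math.isnan(float(x))
    except (TypeError, ValueError):
        return False


def _truthy(x):
    return (not _missing(x)) and bool(x)


def naive_respiratory(pf, sf, imv, support):
    imv = _truthy(imv)
    support = _truthy(support) or imv
    pf_ok = not _missing(pf)
    sf_ok = not _missing(sf)
    if imv and ((pf_ok and pf < 100) or (sf_ok and sf < 148)):
        return 3
    if imv and ((pf_ok and pf < 200) or (sf_ok and sf < 220)):
        return 2
    if support and ((pf_ok and pf < 400) or (sf_ok and sf < 292)):
        return 1
    return 0


def _naive_bracket(age):
    if age < 1:
        return 0
    if age < 12:
        return 1
    if age < 24:
        return 2
    if age < 60:
        return 3
    if age < 144:
        return 4
    return 5


_MAP_CUTS = [(17, 31), (25, 39), (31, 44), (32, 45), (36, 49), (38, 52)]
_CREAT_CUTS = [0.8, 0.3, 0.4, 0.6, 0.7, 1.0]


def naive_cardiovascular(count, lactate, map_mmhg, age):
    pts = 0
    if not _missing(count):
        if count >= 2:
            pts += 2
        elif count == 1:
            pts += 1
    if not _missing(lactate):
        if lactate >= 11:
            pts += 2
        elif lactate >= 5:
            pts += 1
    if not _missing(map_mmhg):
        lo1, lo0 = _MAP_CUTS[_naive_bracket(age)]
        if map_mmhg < lo1:
            pts += 2
        elif map_mmhg < lo0:
            pts += 1
    return pts


def naive_coagulation(platelets, inr, d_dimer, fibrinogen):
    pts = 0
    if not _missing(platelets) and platelets < 100:
        pts += 1
    if not _missing(inr) and inr > 1.3:
        pts += 1
    if not _missing(d_dimer) and d_dimer > 2:
        pts += 1
    if not _missing(fibrinogen) and fibrinogen < 100:
        pts += 1
    return min(pts, 2)


def naive_neurologic(gcs, pupils):
    if _truthy(pupils):
        return 2
    if not _missing(gcs) and gcs <= 10:
        return 1
    return 0


def naive_endocrine(glucose):
    if _missing(glucose):
        return 0
    return 1 if (glucose < 50 or glucose > 150) else 0


def naive_immunologic(anc, alc):
    if (not _missing(anc) and anc < 500) or (not _missing(alc) and alc < 1000):
        return 1
    return 0


def naive_renal(creatinine, age):
    if _missing(creatinine):
        return 0
    return 1 if creatinine >= _CREAT_CUTS[_naive_bracket(age)] else 0


def naive_hepatic(bilirubin, alt):
    if (not _missing(bilirubin) and bilirubin >= 4) or (
        not _missing(alt) and alt > 102
    ):
        return 1
    return 0


def naive_phoenix8_row(row):
    """Score one dict-like row of canonical snapshot columns."""
    resp = naive_respiratory(
        row["pf_ratio"], row["sf_ratio"], row["on_imv"],
        row["on_respiratory_support"],
    )
    cv = naive_cardiovascular(
        row["vasoactive_count"], row["lactate_mmol_l"], row["map_mmhg"],
        row["age_months"],
    )
    coag = naive_coagulation(
        row["platelets_k_ul"], row["inr"], row["d_dimer_mg_l"],
        row["fibrinogen_mg_dl"],
    )
    neuro = naive_neurologic(row["gcs"], row["fixed_pupils_bilateral"])
    endo = naive_endocrine(row["glucose_mg_dl"])
    immu = naive_immunologic(row["anc_cells_mm3"], row["alc_cells_mm3"])
    renal = naive_renal(row["creatinine_mg_dl"], row["age_months"])
    hep = naive_hepatic(row["bilirubin_mg_dl"], row["alt_iu_l"])
    total = resp + cv + coag + neuro
    sepsis = total >= 2
    return {
        "respiratory": resp,
        "cardiovascular": cv,
        "coagulation": coag,
        "neurologic": neuro,
        "endocrine": endo,
        "immunologic": immu,
        "renal": renal,
        "hepatic": hep,
        "total": total,
        "total8": total + endo + immu + renal + hep,
        "sepsis": int(sepsis),
        "septic_shock": int(sepsis and cv >= 1),
    }
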