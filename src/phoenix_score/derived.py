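"""Normalization of raw EHR vitals/labs into canonical scorer inputs.

The scorers consume oxygenation ratios, a single MAP value, and a
vasoactive-agent count; real extracts carry SpO2/FiO2/PaO2, blood
pressures, and per-drug flags. This module does that plumbing:

* :func:`compute_pf_ratio` — PaO2:FiO2.
* :func:`compute_sf_ratio` — SpO2:FiO2, valid only when SpO2 <= 97 %
  (above that, pulse oximetry saturates and the ratio is uninformative,
  so the result is missing).
* :func:`resolve_map` — measured mean arterial pressure preferentially,
  else the pulse-pressure estimate DBP + (SBP - DBP) / 3.
* :func:`count_vasoactives` — count of distinct systemic agents among
  dobutamine, dopamine, epinephrine, milrinone, norepinephrine,
  vasopressin.
* :func:`normalize_fio2` — FiO2 dialect handling: the canonical unit is a
  fraction in [0.21, 1.0]; columns arriving as percentages (values in
  (1, 100]) are rescaled with a single warning.

All functions accept scalars or 1-D array-likes, mirroring the scorers.
"""

from __future__ import annotations

import warnings
from typing import Any, Optional

import numpy as np

from . import _coerce as _c
from .errors import PhoenixValidationError
from .thresholds import SPO2_SF_VALID_MAX, VASOACTIVE_AGENTS

__all__ = [
    "normalize_fio2",
    "compute_pf_ratio",
    "compute_sf_ratio",
    "resolve_map",
    "count_vasoactives",
]

FIO2_MIN = 0.21  # room air


def _ret_float(arr: np.ndarray, scalar: bool):
    if not scalar:
        return arr
    v = float(arr[0])
    return None if np.isnan(v) else v


def normalize_fio2(fio2: Any, field: str = "fio2_fraction"):
    """Return FiO2 as a fraction in [0.21, 1.0].

    Values in (1, 100] are interpreted as percentages and divided by 100,
    with one warning per call (per column, not per row). Values below 0.21
    after rescaling, or above 100, are validation errors.
    """
    arr, scalar = _c.float_col(fio2, field)
    arr = arr.astype(float).copy()
    pct = arr > 1.0
    if pct.any():
        too_big = arr > 100.0
        if too_big.any():
            raise PhoenixValidationError(
                field,
                "FiO2 above 100 is neither a fraction nor a percentage",
                rows=None if scalar else list(np.flatnonzero(too_big)),
            )
        warnings.warn(
            f"{field}: values > 1 interpreted as percentages and rescaled "
            "to fractions",
            stacklevel=2,
        )
        arr[pct] = arr[pct] / 100.0
    low = np.isfinite(arr) & (arr < FIO2_MIN)
    if low.any():
        raise PhoenixValidationError(
            field,
            f"FiO2 fraction below {FIO2_MIN} (room air) is not physiologic",
            rows=None if scalar else list(np.flatnonzero(low)),
        )
    return _ret_float(arr, scalar)


def compute_pf_ratio(pao2_mmhg: Any = None, fio2_fraction: Any = None):
    """PaO2:FiO2 ratio; missing when either input is missing."""
    pao2, s1 = _c.float_col(pao2_mmhg, "pao2_mmhg")
    fio2 = normalize_fio2(fio2_fraction)
    fio2, s2 = _c.float_col(fio2, "fio2_fraction")
    pao2, fio2 = _c.broadcast(pao2, fio2)
    return _ret_float(pao2 / fio2, s1 and s2)


def compute_sf_ratio(spo2_pct: Any = None, fio2_fraction: Any = None):
    """SpO2:FiO2 ratio, gated to SpO2 <= 97 %.

    Returns missing when SpO2 exceeds 97 (the ratio is not a valid
    oxygenation surrogate there) or when either input is missing.
    """
    spo2, s1 = _c.float_col(spo2_pct, "spo2_pct")
    over = spo2 > 100.0
    if over.any():
        raise PhoenixValidationError(
            "spo2_pct",
            "SpO2 is a percentage in [0, 100]",
            rows=None if s1 else list(np.flatnonzero(over)),
        )
    fio2 = normalize_fio2(fio2_fraction)
    fio2, s2 = _c.float_col(fio2, "fio2_fraction")
    spo2, fio2 = _c.broadcast(spo2, fio2)
    ratio = np.where(spo2 <= SPO2_SF_VALID_MAX, spo2 / fio2, np.nan)
    return _ret_float(ratio, s1 and s2)


def resolve_map(
    map_measured_mmhg: Any = None,
    sbp_mmhg: Any = None,
    dbp_mmhg: Any = None,
):
    """Mean arterial pressure with the measured-value preference.

    A measured MAP (invasive arterial or oscillometric) is used whenever
    present; otherwise MAP is estimated as DBP + (SBP - DBP) / 3; missing
    when neither is available. DBP above SBP is a validation error.
    """
    mp, s1 = _c.float_col(map_measured_mmhg, "map_measured_mmhg")
    sbp, s2 = _c.float_col(sbp_mmhg, "sbp_mmhg")
    dbp, s3 = _c.float_col(dbp_mmhg, "dbp_mmhg")
    mp, sbp, dbp = _c.broadcast(mp, sbp, dbp)

    bad = np.isfinite(sbp) & np.isfinite(dbp) & (dbp > sbp)
    scalar = s1 and s2 and s3
    if bad.any():
        raise PhoenixValidationError(
            "dbp_mmhg",
            "diastolic pressure exceeds systolic",
            rows=None if scalar else list(np.flatnonzero(bad)),
        )
    estimated = dbp + (sbp - dbp) / 3.0
    out = np.where(np.isfinite(mp), mp, estimated)
    return _ret_float(out, scalar)


def count_vasoactives(
    dobutamine: Any = None,
    dopamine: Any = None,
    epinephrine: Any = None,
    milrinone: Any = None,
    norepinephrine: Any = None,
    vasopressin: Any = None,
):
    """Count of distinct systemic vasoactive agents (0-6).

    Missing flags count as not-administered. Order of keyword arguments
    matches :data:`phoenix_score.thresholds.VASOACTIVE_AGENTS`.
    """
    flags = (dobutamine, dopamine, epinephrine, milrinone, norepinephrine,
             vasopressin)
    cols = []
    scalar = True
    for name, flag in zip(VASOACTIVE_AGENTS, flags):
        col, s = _c.bool_col(flag, name)
        cols.append(col)
        scalar = scalar and s
    cols = _c.broadcast(*cols)
    total = np.sum(np.stack(cols, axis=0), axis=0).astype(np.int64)
    return int(total[0]) if scalar else total


class RawVitalsLabs:
    """One patient's raw vitals in EHR form, normalized on construction.

    Convenience wrapper for scalar use: validates SpO2/FiO2/blood-pressure
    consistency and exposes the canonical snapshot inputs via
    :meth:`snapshot_inputs`.
    """

    def __init__(
        self,
        spo2_pct: Optional[float] = None,
        fio2_fraction: Optional[float] = None,
        pao2_mmhg: Optional[float] = None,
        map_measured_mmhg: Optional[float] = None,
        sbp_mmhg: Optional[float] = None,
        dbp_mmhg: Optional[float] = None,
        dobutamine: Optional[bool] = None,
        dopamine: Optional[bool] = None,
        epinephrine: Optional[bool] = None,
        milrinone: Optional[bool] = None,
        norepinephrine: Optional[bool] = None,
        vasopressin: Optional[bool] = None,
    ) -> None:
        self.spo2_pct = spo2_pct
        self.fio2_fraction = (
            normalize_fio2(fio2_fraction) if fio2_fraction is not None else None
        )
        self.pao2_mmhg = pao2_mmhg
        self.map_measured_mmhg = map_measured_mmhg
        self.sbp_mmhg = sbp_mmhg
        self.dbp_mmhg = dbp_mmhg
        self.vasoactives = dict(
            zip(
                VASOACTIVE_AGENTS,
                (dobutamine, dopamine, epinephrine, milrinone,
                 norepinephrine, vasopressin),
            )
        )
        # trigger DBP/SBP consistency validation eagerly
        resolve_map(map_measured_mmhg, sbp_mmhg, dbp_mmhg)

    def snapshot_inputs(self) -> dict:
        """Canonical scorer inputs derived from the raw fields."""
        return {
            "pf_ratio": compute_pf_ratio(self.pao2_mmhg, self.fio2_fraction),
            "sf_ratio": compute_sf_ratio(self.spo2_pct, self.fio2_fraction),
            "map_mmhg": resolve_map(
                self.map_measured_mmhg, self.sbp_mmhg, self.dbp_mmhg
            ),
            "vasoactive_count": count_vasoactives(**self.vasoactives),
        }
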