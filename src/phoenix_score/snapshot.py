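"""Patient snapshot and score-result containers.

A :class:`PatientSnapshot` holds one patient/encounter's raw inputs in
canonical units. Every field except ``age_months`` may be ``None``
(missing); missing is a first-class state distinct from zero and always
contributes zero points downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Any, Dict, Optional

from .errors import PhoenixValidationError

__all__ = ["PatientSnapshot", "PhoenixResult", "Phoenix8Result"]

_NONNEG_FIELDS = (
    "pf_ratio",
    "sf_ratio",
    "lactate_mmol_l",
    "map_mmhg",
    "platelets_k_ul",
    "inr",
    "d_dimer_mg_l",
    "fibrinogen_mg_dl",
    "glucose_mg_dl",
    "anc_cells_mm3",
    "alc_cells_mm3",
    "creatinine_mg_dl",
    "bilirubin_mg_dl",
    "alt_iu_l",
)
_BOOL_FIELDS = ("on_imv", "on_respiratory_support", "fixed_pupils_bilateral")


def _norm_missing(value: Any) -> Any:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return value


@dataclass(frozen=True)
class PatientSnapshot:
    """One patient/encounter's inputs to the Phoenix scoring rubric.

    Units: age in months (not adjusted for prematurity); lactate mmol/L;
    MAP mmHg; platelets 10^3/uL; D-dimer mg/L FEU; fibrinogen mg/dL;
    glucose, creatinine, bilirubin mg/dL; ALT IU/L; ANC/ALC cells/mm^3;
    PF and SF ratios unitless (SF only valid when SpO2 <= 97, gated
    upstream); GCS an integer 3-15.
    """

    age_months: float
    pf_ratio: Optional[float] = None
    sf_ratio: Optional[float] = None
    on_imv: Optional[bool] = None
    on_respiratory_support: Optional[bool] = None
    vasoactive_count: Optional[int] = None
    lactate_mmol_l: Optional[float] = None
    map_mmhg: Optional[float] = None
    platelets_k_ul: Optional[float] = None
    inr: Optional[float] = None
    d_dimer_mg_l: Optional[float] = None
    fibrinogen_mg_dl: Optional[float] = None
    gcs: Optional[int] = None
    fixed_pupils_bilateral: Optional[bool] = None
    glucose_mg_dl: Optional[float] = None
    anc_cells_mm3: Optional[float] = None
    alc_cells_mm3: Optional[float] = None
    creatinine_mg_dl: Optional[float] = None
    bilirubin_mg_dl: Optional[float] = None
    alt_iu_l: Optional[float] = None

    def __post_init__(self) -> None:
        set_ = object.__setattr__
        age = _norm_missing(self.age_months)
        if age is None:
            raise PhoenixValidationError("age_months", "age is required")
        age = float(age)
        if age < 0:
            raise PhoenixValidationError(
                "age_months", "age must be non-negative"
            )
        set_(self, "age_months", age)

        for name in _NONNEG_FIELDS:
            v = _norm_missing(getattr(self, name))
            if v is not None:
                v = float(v)
                if v < 0:
                    raise PhoenixValidationError(
                        name, "negative value not allowed"
                    )
            set_(self, name, v)

        for name in _BOOL_FIELDS:
            v = _norm_missing(getattr(self, name))
            if v is not None:
                if isinstance(v, (int, float)) and not isinstance(v, bool):
                    if float(v) not in (0.0, 1.0):
                        raise PhoenixValidationError(
                            name, f"boolean flag must be 0/1, got {v!r}"
                        )
                v = bool(v)
            set_(self, name, v)

        cnt = _norm_missing(self.vasoactive_count)
        if cnt is not None:
            if float(cnt) != int(cnt) or not 0 <= int(cnt) <= 6:
                raise PhoenixValidationError(
                    "vasoactive_count", "must be an integer between 0 and 6"
                )
            cnt = int(cnt)
        set_(self, "vasoactive_count", cnt)

        g = _norm_missing(self.gcs)
        if g is not None:
            if float(g) != int(g) or not 3 <= int(g) <= 15:
                raise PhoenixValidationError(
                    "gcs", "must be an integer between 3 and 15"
                )
            g = int(g)
        set_(self, "gcs", g)

        # invasive mechanical ventilation is a form of respiratory support
        if self.on_imv and not self.on_respiratory_support:
            set_(self, "on_respiratory_support", True)

    @classmethod
    def field_names(cls) -> tuple:
        return tuple(f.name for f in fields(cls))


@dataclass(frozen=True)
class PhoenixResult:
    """4-system Phoenix score with sepsis / septic-shock indicators.

    The indicators are the score-based criteria only (sepsis: total >= 2;
    septic shock: sepsis with >= 1 cardiovascular point); the
    suspected-infection component of the clinical definition is not
    evaluated by this package.
    """

    respiratory: int
    cardiovascular: int
    coagulation: int
    neurologic: int
    total: int
    sepsis: bool
    septic_shock: bool

    def as_dict(self) -> Dict[str, int]:
        """Flat dict with flags encoded as 0/1 integers (file convention)."""
        return {
            "respiratory": self.respiratory,
            "cardiovascular": self.cardiovascular,
            "coagulation": self.coagulation,
            "neurologic": self.neurologic,
            "total": self.total,
            "sepsis": int(self.sepsis),
            "septic_shock": int(self.septic_shock),
        }


@dataclass(frozen=True)
class Phoenix8Result(PhoenixResult):
    """Phoenix-8 result: the 4-system fields plus endocrine, immunologic,
    renal, and hepatic sub-scores and the 8-system total (0-17). The
    extra systems never affect the sepsis or septic-shock flags."""

    endocrine: int = 0
    immunologic: int = 0
    renal: int = 0
    hepatic: int = 0
    total8: int = 0

    def as_dict(self) -> Dict[str, int]:
        out = super().as_dict()
        out.update(
            endocrine=self.endocrine,
            immunologic=self.immunologic,
            renal=self.renal,
            hepatic=self.hepatic,
            total8=self.total8,
        )
        return out
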