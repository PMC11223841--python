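"""Declarative threshold tables for the Phoenix pediatric sepsis rubric.

Every cut-point used anywhere in the package lives in this module, so the
whole rubric can be reviewed in one place. Comparisons are performed on
floating-point values exactly as written here; no rounding is applied to
lactate, MAP, or any lab before comparison.

Conventions:

* Age is measured in months and is not adjusted for prematurity.
* Age brackets are half-open ``[lo, hi)`` and contiguous over ``[0, 216)``.
* For MAP (mean arterial pressure, mmHg): 2 points below ``map_1pt_lower``,
  1 point in ``[map_1pt_lower, map_0pt_lower)``, 0 at or above
  ``map_0pt_lower``.
* For creatinine (mg/dL): 1 point at or above ``creatinine_1pt_lower``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = [
    "AgeBracket",
    "AGE_BRACKETS",
    "AGE_BRACKET_EDGES",
    "MAX_AGE_MONTHS",
    "MAP_1PT_LOWER",
    "MAP_0PT_LOWER",
    "CREATININE_1PT_LOWER",
    "bracket_index",
]


@dataclass(frozen=True)
class AgeBracket:
    """One age bracket with its MAP and creatinine cut-points."""

    lo_months: float
    hi_months: float
    map_1pt_lower: float  # mmHg; below this MAP scores 2 points
    map_0pt_lower: float  # mmHg; at/above this MAP scores 0 points
    creatinine_1pt_lower: float  # mg/dL; at/above this scores 1 point


#: The six age brackets (months, half-open) with age-adjusted cut-points.
AGE_BRACKETS: Tuple[AgeBracket, ...] = (
    AgeBracket(0.0, 1.0, 17.0, 31.0, 0.8),
    AgeBracket(1.0, 12.0, 25.0, 39.0, 0.3),
    AgeBracket(12.0, 24.0, 31.0, 44.0, 0.4),
    AgeBracket(24.0, 60.0, 32.0, 45.0, 0.6),
    AgeBracket(60.0, 144.0, 36.0, 49.0, 0.7),
    AgeBracket(144.0, 216.0, 38.0, 52.0, 1.0),
)

AGE_BRACKET_EDGES: np.ndarray = np.array(
    [b.lo_months for b in AGE_BRACKETS] + [AGE_BRACKETS[-1].hi_months]
)
MAX_AGE_MONTHS: float = float(AGE_BRACKET_EDGES[-1])  # 216 months = 18 years

MAP_1PT_LOWER: np.ndarray = np.array([b.map_1pt_lower for b in AGE_BRACKETS])
MAP_0PT_LOWER: np.ndarray = np.array([b.map_0pt_lower for b in AGE_BRACKETS])
CREATININE_1PT_LOWER: np.ndarray = np.array(
    [b.creatinine_1pt_lower for b in AGE_BRACKETS]
)

# --- Respiratory (0-3 points) -------------------------------------------
# Tier upper bounds for the PaO2:FiO2 and SpO2:FiO2 ratios. A ratio below
# the tier bound (strict <) satisfies that tier; tiers 2 and 3 additionally
# require invasive mechanical ventilation, tier 1 any respiratory support.
PF_1PT_UPPER = 400.0
PF_2PT_UPPER = 200.0
PF_3PT_UPPER = 100.0
SF_1PT_UPPER = 292.0
SF_2PT_UPPER = 220.0
SF_3PT_UPPER = 148.0

#: SpO2:FiO2 is only a valid oxygenation surrogate when SpO2 <= 97 %.
SPO2_SF_VALID_MAX = 97.0

# --- Cardiovascular (0-6 points) ----------------------------------------
LACTATE_1PT_LOWER = 5.0  # mmol/L; 1 point for 5 <= lactate < 11
LACTATE_2PT_LOWER = 11.0  # mmol/L; 2 points at/above

#: Systemic vasoactive agents counted toward the medication sub-component.
VASOACTIVE_AGENTS: Tuple[str, ...] = (
    "dobutamine",
    "dopamine",
    "epinephrine",
    "milrinone",
    "norepinephrine",
    "vasopressin",
)

# --- Coagulation (0-2 points; 1 per abnormal lab, capped at 2) ----------
PLATELETS_1PT_UPPER = 100.0  # 10^3/uL; strict <
INR_1PT_ABOVE = 1.3  # strict >
DDIMER_1PT_ABOVE = 2.0  # mg/L FEU; strict >
FIBRINOGEN_1PT_UPPER = 100.0  # mg/dL; strict <

# --- Neurologic (0-2 points) --------------------------------------------
GCS_1PT_MAX = 10  # GCS <= 10 scores 1 point; bilaterally fixed pupils 2

# --- Endocrine (0-1 point) ----------------------------------------------
GLUCOSE_LOW = 50.0  # mg/dL; 1 point strictly below
GLUCOSE_HIGH = 150.0  # mg/dL; 1 point strictly above

# --- Immunologic (0-1 point) --------------------------------------------
ANC_1PT_UPPER = 500.0  # cells/mm^3; strict <
ALC_1PT_UPPER = 1000.0  # cells/mm^3; strict <

# --- Hepatic (0-1 point) ------------------------------------------------
BILIRUBIN_1PT_LOWER = 4.0  # mg/dL total bilirubin; >= 4 scores
ALT_1PT_ABOVE = 102.0  # IU/L; strict >


def bracket_index(age_months: np.ndarray) -> np.ndarray:
    """Return the age-bracket index (0-5) for ages already validated to
    lie in ``[0, 216)``. Vectorized; does not itself validate."""
    return np.clip(
        np.searchsorted(AGE_BRACKET_EDGES[1:], age_months, side="right"),
        0,
        len(AGE_BRACKETS) - 1,
    ).astype(np.intp)
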