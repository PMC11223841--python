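"""Reading, scoring, and writing delimited patient tables.

The input is a CSV/TSV with one row per patient/encounter snapshot. A
:class:`ColumnMapping` binds the file's column names to canonical field
names; unmapped fields are simply absent (missing for every row). Columns
may carry either raw EHR fields (SpO2, FiO2, PaO2, SBP/DBP, per-drug
vasoactive flags) or precomputed canonical inputs (``pf_ratio``,
``sf_ratio``, ``map_mmhg``, ``vasoactive_count``); when both are mapped the
precomputed column wins.

Score output is a table with one row per input row: the four Phoenix
sub-scores, the total, and 0/1 sepsis / septic-shock indicator columns
(7 columns), or the 12-column Phoenix-8 layout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import scoring
from .derived import (
    compute_pf_ratio,
    compute_sf_ratio,
    count_vasoactives,
    normalize_fio2,
    resolve_map,
)
from .errors import PhoenixValidationError
from .snapshot import PatientSnapshot
from .thresholds import VASOACTIVE_AGENTS

__all__ = [
    "ColumnMapping",
    "Cohort",
    "RowError",
    "read_cohort",
    "score_table",
    "write_scores",
    "PHOENIX_COLUMNS",
    "PHOENIX8_COLUMNS",
]

logger = logging.getLogger("phoenix_score")

PHOENIX_COLUMNS = (
    "respiratory",
    "cardiovascular",
    "coagulation",
    "neurologic",
    "total",
    "sepsis",
    "septic_shock",
)
PHOENIX8_COLUMNS = PHOENIX_COLUMNS + (
    "endocrine",
    "immunologic",
    "renal",
    "hepatic",
    "total8",
)

_RAW_NUMERIC_FIELDS = (
    "age_months",
    "spo2_pct",
    "fio2_fraction",
    "pao2_mmhg",
    "sbp_mmhg",
    "dbp_mmhg",
    "map_measured_mmhg",
    "lactate_mmol_l",
    "platelets_k_ul",
    "inr",
    "d_dimer_mg_l",
    "fibrinogen_mg_dl",
    "gcs",
    "glucose_mg_dl",
    "anc_cells_mm3",
    "alc_cells_mm3",
    "creatinine_mg_dl",
    "bilirubin_mg_dl",
    "alt_iu_l",
    "pf_ratio",
    "sf_ratio",
    "map_mmhg",
    "vasoactive_count",
)
_RAW_BOOL_FIELDS = (
    "on_imv",
    "on_respiratory_support",
    "fixed_pupils_bilateral",
) + VASOACTIVE_AGENTS

#: Every canonical field a column may be mapped to.
CANONICAL_FIELDS = ("row_id",) + _RAW_NUMERIC_FIELDS + _RAW_BOOL_FIELDS

#: Column names used by the bundled synthetic cohort (no config needed).
DEFAULT_MAPPING: Dict[str, str] = {
    "row_id": "pid",
    "age_months": "age",
    "spo2_pct": "spo2",
    "fio2_fraction": "fio2",
    "pao2_mmhg": "pao2",
    "on_imv": "vent",
    "dobutamine": "dobutamine",
    "dopamine": "dopamine",
    "epinephrine": "epinephrine",
    "milrinone": "milrinone",
    "norepinephrine": "norepinephrine",
    "vasopressin": "vasopressin",
    "sbp_mmhg": "sbp",
    "dbp_mmhg": "dbp",
    "lactate_mmol_l": "lactate",
    "platelets_k_ul": "platelets",
    "inr": "inr",
    "d_dimer_mg_l": "d_dimer",
    "fibrinogen_mg_dl": "fibrinogen",
    "gcs": "gcs",
    "fixed_pupils_bilateral": "fixed_pupils",
    "glucose_mg_dl": "glucose",
    "anc_cells_mm3": "anc",
    "alc_cells_mm3": "alc",
    "creatinine_mg_dl": "creatinine",
    "bilirubin_mg_dl": "bilirubin",
    "alt_iu_l": "alt",
}

_TRUE_TOKENS = {"1", "1.0", "true", "t", "yes", "y"}
_FALSE_TOKENS = {"0", "0.0", "false", "f", "no", "n"}


@dataclass(frozen=True)
class ColumnMapping:
    """Binding of canonical field names to input-table column names."""

    fields: Dict[str, str]

    def __post_init__(self) -> None:
        unknown = sorted(set(self.fields) - set(CANONICAL_FIELDS))
        if unknown:
            raise PhoenixValidationError(
                "mapping", f"unknown canonical field(s): {', '.join(unknown)}"
            )
        seen: Dict[str, str] = {}
        for canon, col in self.fields.items():
            if col in seen:
                raise PhoenixValidationError(
                    "mapping",
                    f"column {col!r} mapped to both "
                    f"{seen[col]!r} and {canon!r}",
                )
            seen[col] = canon

    @classmethod
    def default(cls) -> "ColumnMapping":
        return cls(dict(DEFAULT_MAPPING))

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ColumnMapping":
        """Load a mapping from YAML or JSON (chosen by file extension).

        The file is a flat mapping of canonical field name to column name.
        """
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise PhoenixValidationError(
                "mapping", f"{path} must contain a flat field->column mapping"
            )
        return cls({str(k): str(v) for k, v in data.items()})

    def validate_columns(self, columns: Iterable[str]) -> None:
        cols = set(columns)
        missing = sorted(c for c in self.fields.values() if c not in cols)
        if missing:
            raise PhoenixValidationError(
                "mapping",
                f"mapped column(s) not present in input: {', '.join(missing)}",
            )

    def column_for(self, canonical: str) -> Optional[str]:
        return self.fields.get(canonical)


@dataclass(frozen=True)
class RowError:
    """One row-level validation failure (1-based data-row number)."""

    row: int
    column: str
    message: str


@dataclass
class Cohort:
    """Parsed snapshots plus preserved row identifiers and any row errors
    collected in lenient mode. ``row_ids[i]`` identifies ``snapshots[i]``."""

    snapshots: List[PatientSnapshot]
    row_ids: Optional[List] = None
    errors: List[RowError] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.snapshots)


def _parse_float(token: str) -> Optional[float]:
    token = token.strip()
    if token == "" or token.lower() in ("na", "nan", "null", "none"):
        return None
    return float(token)


def _parse_bool(token: str) -> Optional[bool]:
    token = token.strip().lower()
    if token == "" or token in ("na", "nan", "null", "none"):
        return None
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise ValueError(f"not a boolean: {token!r}")


def read_cohort(
    path: Union[str, Path],
    mapping: Optional[ColumnMapping] = None,
    *,
    sep: str = ",",
    lenient: bool = False,
) -> Cohort:
    """Read a delimited patient table into validated snapshots.

    Empty cells are missing. Raw respiratory/pressure/vasoactive columns
    are normalized through the derived-input functions (SF-ratio validity
    gating, MAP hierarchy, FiO2 percent rescaling, drug-flag counting).
    By default the first invalid cell aborts with a row/column-labelled
    error; with ``lenient=True`` invalid rows are dropped and reported in
    ``Cohort.errors`` instead.
    """
    mapping = mapping or ColumnMapping.default()
    try:
        frame = pd.read_csv(
            path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8"
        )
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise PhoenixValidationError("input", f"cannot read {path}: {exc}")
    mapping.validate_columns(frame.columns)

    def cell(canonical: str, row: pd.Series) -> str:
        col = mapping.column_for(canonical)
        return "" if col is None else str(row[col])

    # FiO2 percent-vs-fraction detection is a column-level decision: scan
    # once so percent files rescale uniformly (and warn once).
    fio2_is_pct = False
    fio2_col = mapping.column_for("fio2_fraction")
    if fio2_col is not None:
        vals = [
            _parse_float(v)
            for v in frame[fio2_col]
            if v.strip() not in ("", "na", "nan", "null", "none")
        ]
        vals = [v for v in vals if v is not None]
        if vals and max(vals) > 1.0:
            fio2_is_pct = True
            logger.warning(
                "column %r: FiO2 values > 1 interpreted as percentages and "
                "rescaled to fractions",
                fio2_col,
            )

    snapshots: List[PatientSnapshot] = []
    row_ids: List = []
    errors: List[RowError] = []
    id_col = mapping.column_for("row_id")

    for i, (_, row) in enumerate(frame.iterrows()):
        rownum = i + 1  # 1-based data-row number
        try:
            num: Dict[str, Optional[float]] = {}
            for canon in _RAW_NUMERIC_FIELDS:
                col = mapping.column_for(canon)
                if col is None:
                    num[canon] = None
                    continue
                try:
                    num[canon] = _parse_float(str(row[col]))
                except ValueError:
                    raise PhoenixValidationError(
                        col,
                        f"cannot interpret {row[col]!r} as a number",
                        rows=[rownum],
                    ) from None
            boo: Dict[str, Optional[bool]] = {}
            for canon in _RAW_BOOL_FIELDS:
                col = mapping.column_for(canon)
                if col is None:
                    boo[canon] = None
                    continue
                try:
                    boo[canon] = _parse_bool(str(row[col]))
                except ValueError:
                    raise PhoenixValidationError(
                        col,
                        f"cannot interpret {row[col]!r} as a boolean",
                        rows=[rownum],
                    ) from None

            fio2 = num["fio2_fraction"]
            if fio2 is not None and fio2_is_pct:
                fio2 = fio2 / 100.0
            if fio2 is not None:
                fio2 = normalize_fio2(fio2)

            pf = num["pf_ratio"]
            if pf is None:
                pf = compute_pf_ratio(num["pao2_mmhg"], fio2)
            sf = num["sf_ratio"]
            if sf is None:
                sf = compute_sf_ratio(num["spo2_pct"], fio2)
            mp = num["map_mmhg"]
            if mp is None:
                mp = resolve_map(
                    num["map_measured_mmhg"], num["sbp_mmhg"], num["dbp_mmhg"]
                )
            cnt = num["vasoactive_count"]
            if cnt is None:
                flags = {a: boo[a] for a in VASOACTIVE_AGENTS}
                if any(v is not None for v in flags.values()):
                    cnt = count_vasoactives(**flags)

            snapshots.append(
                PatientSnapshot(
                    age_months=num["age_months"],
                    pf_ratio=pf,
                    sf_ratio=sf,
                    on_imv=boo["on_imv"],
                    on_respiratory_support=boo["on_respiratory_support"],
                    vasoactive_count=cnt,
                    lactate_mmol_l=num["lactate_mmol_l"],
                    map_mmhg=mp,
                    platelets_k_ul=num["platelets_k_ul"],
                    inr=num["inr"],
                    d_dimer_mg_l=num["d_dimer_mg_l"],
                    fibrinogen_mg_dl=num["fibrinogen_mg_dl"],
                    gcs=num["gcs"],
                    fixed_pupils_bilateral=boo["fixed_pupils_bilateral"],
                    glucose_mg_dl=num["glucose_mg_dl"],
                    anc_cells_mm3=num["anc_cells_mm3"],
                    alc_cells_mm3=num["alc_cells_mm3"],
                    creatinine_mg_dl=num["creatinine_mg_dl"],
                    bilirubin_mg_dl=num["bilirubin_mg_dl"],
                    alt_iu_l=num["alt_iu_l"],
                )
            )
            row_ids.append(row[id_col] if id_col is not None else rownum)
        except PhoenixValidationError as exc:
            err = RowError(row=rownum, column=exc.field, message=str(exc))
            if not lenient:
                raise PhoenixValidationError(
                    exc.field, f"row {rownum}: {exc}", rows=[rownum]
                ) from exc
            logger.warning("skipping row %d: %s", rownum, exc)
            errors.append(err)

    return Cohort(snapshots=snapshots, row_ids=row_ids, errors=errors)


def score_table(
    snapshots: Union[Cohort, Sequence[PatientSnapshot]],
    mode: str = "phoenix",
    *,
    row_ids: Optional[Sequence] = None,
    clamp_age: bool = False,
) -> pd.DataFrame:
    """Score a cohort element-wise into a tidy integer table.

    ``mode`` selects the 7-column Phoenix layout or the 12-column
    Phoenix-8 layout; sub-scores and totals are integers and the sepsis /
    septic-shock flags are 0/1. Row order is preserved and an ``id``
    column is prepended when row identifiers are available.
    """
    if mode not in ("phoenix", "phoenix8"):
        raise ValueError(f"mode must be 'phoenix' or 'phoenix8', got {mode!r}")
    if isinstance(snapshots, Cohort):
        if row_ids is None:
            row_ids = snapshots.row_ids
        snapshots = snapshots.snapshots

    def col(name: str, dtype=float) -> np.ndarray:
        if dtype is float:
            return np.array(
                [
                    np.nan if getattr(s, name) is None else getattr(s, name)
                    for s in snapshots
                ],
                dtype=float,
            )
        return np.array([getattr(s, name) for s in snapshots], dtype=object)

    n = len(snapshots)
    resp = scoring.score_respiratory(
        col("pf_ratio"), col("sf_ratio"), col("on_imv", object),
        col("on_respiratory_support", object),
    )
    cv = scoring.score_cardiovascular(
        col("vasoactive_count"), col("lactate_mmol_l"), col("map_mmhg"),
        col("age_months"), clamp_age=clamp_age,
    )
    coag = scoring.score_coagulation(
        col("platelets_k_ul"), col("inr"), col("d_dimer_mg_l"),
        col("fibrinogen_mg_dl"),
    )
    neuro = scoring.score_neurologic(
        col("gcs"), col("fixed_pupils_bilateral", object)
    )
    total = resp + cv + coag + neuro
    sepsis = (total >= 2).astype(np.int64)
    shock = ((total >= 2) & (cv >= 1)).astype(np.int64)

    data = {
        "respiratory": resp,
        "cardiovascular": cv,
        "coagulation": coag,
        "neurologic": neuro,
        "total": total,
        "sepsis": sepsis,
        "septic_shock": shock,
    }
    if mode == "phoenix8":
        endo = scoring.score_endocrine(col("glucose_mg_dl"))
        immu = scoring.score_immunologic(
            col("anc_cells_mm3"), col("alc_cells_mm3")
        )
        renal = scoring.score_renal(
            col("creatinine_mg_dl"), col("age_months"), clamp_age=clamp_age
        )
        hep = scoring.score_hepatic(col("bilirubin_mg_dl"), col("alt_iu_l"))
        data.update(
            endocrine=endo,
            immunologic=immu,
            renal=renal,
            hepatic=hep,
            total8=total + endo + immu + renal + hep,
        )

    out = pd.DataFrame({k: np.asarray(v, dtype=np.int64) for k, v in data.items()})
    if n == 0:  # keep headers on empty input
        out = out.astype(np.int64)
    if row_ids is not None:
        out.insert(0, "id", list(row_ids))
    return out


def write_scores(
    table: pd.DataFrame, path: Union[str, Path], *, sep: str = ","
) -> None:
    """Write a score table as CSV/TSV with a deterministic column order;
    integers are written without decimal points."""
    table.to_csv(path, sep=sep, index=False, lineterminator="\n")
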