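"""Shared scalar-or-array input coercion for the scoring and derived-input
functions. Missing values (None/NaN) become NaN in float columns and False
in boolean columns; scalar-only inputs yield scalar outputs."""

from __future__ import annotations

from typing import Any, Tuple

import numpy as np

from .errors import PhoenixValidationError


def is_scalar(x: Any) -> bool:
    if x is None:
        return True
    if isinstance(x, np.ndarray):
        return x.ndim == 0
    return np.isscalar(x)


def float_col(
    x: Any, field: str, *, check_negative: bool = True
) -> Tuple[np.ndarray, bool]:
    """Coerce to a 1-D float array with NaN for missing; reject negatives."""
    scalar = is_scalar(x)
    if scalar:
        if x is None:
            arr = np.array([np.nan])
        else:
            try:
                arr = np.array([float(x)])
            except (TypeError, ValueError):
                raise PhoenixValidationError(
                    field, f"cannot interpret {x!r} as a number"
                ) from None
    else:
        try:
            arr = np.asarray(x, dtype=float).ravel()
        except (TypeError, ValueError):
            # object arrays with e.g. strings: locate offenders row by row
            vals = list(np.asarray(x, dtype=object).ravel())
            bad = []
            for i, v in enumerate(vals):
                if v is None:
                    continue
                try:
                    float(v)
                except (TypeError, ValueError):
                    bad.append(i)
            raise PhoenixValidationError(
                field, "non-numeric value", rows=bad
            ) from None
    if check_negative:
        neg = arr < 0
        if neg.any():
            raise PhoenixValidationError(
                field,
                "negative value not allowed",
                rows=None if scalar else list(np.flatnonzero(neg)),
            )
    return arr, scalar


def bool_col(x: Any, field: str) -> Tuple[np.ndarray, bool]:
    """Coerce to a 1-D bool array; missing (None/NaN) maps to False."""
    scalar = is_scalar(x)
    if scalar:
        vals = [x]
    else:
        vals = list(np.asarray(x, dtype=object).ravel())
    out = np.empty(len(vals), dtype=bool)
    for i, v in enumerate(vals):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            out[i] = False
        elif isinstance(v, (bool, np.bool_)):
            out[i] = bool(v)
        elif isinstance(v, (int, np.integer, float, np.floating)):
            if float(v) not in (0.0, 1.0):
                raise PhoenixValidationError(
                    field,
                    f"boolean flag must be 0/1, got {v!r}",
                    rows=None if scalar else [i],
                )
            out[i] = bool(v)
        else:
            raise PhoenixValidationError(
                field,
                f"cannot interpret {v!r} as a boolean",
                rows=None if scalar else [i],
            )
    return out, scalar


def broadcast(*cols: np.ndarray) -> Tuple[np.ndarray, ...]:
    lengths = {c.shape[0] for c in cols}
    lengths.discard(1)
    if len(lengths) > 1:
        raise PhoenixValidationError(
            "inputs", f"array inputs have incompatible lengths {sorted(lengths)}"
        )
    n = lengths.pop() if lengths else 1
    return tuple(np.broadcast_to(c, (n,)) for c in cols)
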