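"""Validation errors raised while building snapshots or scoring tables."""

from __future__ import annotations

from typing import Optional, Sequence

__all__ = ["PhoenixValidationError"]


class PhoenixValidationError(ValueError):
    """Invalid input to a scorer or snapshot.

    Carries the offending field name and, for table inputs, the 0-based row
    indices at fault so callers can report them back to the user.
    """

    def __init__(
        self,
        field: str,
        message: str,
        rows: Optional[Sequence[int]] = None,
    ) -> None:
        self.field = field
        self.rows = None if rows is None else list(rows)
        detail = f"{field}: {message}"
        if self.rows is not None:
            shown = ", ".join(str(r) for r in self.rows[:10])
            more = "" if len(self.rows) <= 10 else f" (+{len(self.rows) - 10} more)"
            detail += f" [rows: {shown}{more}]"
        super().__init__(detail)
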