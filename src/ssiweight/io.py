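"""Trial-table CSV I/O with schema and invariant validation.

The long-format trial table (UTF-8, comma-separated, header row, empty
fields for values not applicable to a condition) is the pipeline's sole
interchange format.  Reading validates the interval-condition rows against
the splitting-procedure invariants — ordered limits, nesting, midpoint
consistency — and reports offending rows by number.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ssiweight.exceptions import EmptyInputError, TrialTableValidationError
from ssiweight.simulate import TRIAL_COLUMNS

_ANSWER_COLS = ["a1", "a2", "a3"]


def write_trial_table(table: pd.DataFrame, path) -> None:
    """Write a trial table CSV; column order is normalized to the schema."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise TrialTableValidationError(f"table lacks columns: {missing}")
    table[TRIAL_COLUMNS].to_csv(path, index=False)


def validate_trial_table(table: pd.DataFrame) -> None:
    """Raise with row numbers if any interval row breaks the SSI invariants."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise TrialTableValidationError(f"table lacks columns: {missing}")
    bad: set[int] = set()
    ssi = table[table["condition"] == "ssi"]
    for k in range(1, 5):
        lo, up = ssi[f"l{k}"], ssi[f"u{k}"]
        bad.update(ssi.index[~(up > lo)])
        mid = ssi[f"mid{k}"]
        bad.update(ssi.index[~np.isclose(mid, (lo + up) / 2)])
        if k > 1:
            # nesting: each interval inside its parent, sharing one endpoint
            plo, pup = ssi[f"l{k-1}"], ssi[f"u{k-1}"]
            nested = (lo >= plo) & (up <= pup)
            shares = np.isclose(lo, plo) | np.isclose(up, pup)
            bad.update(ssi.index[~(nested & shares)])
    answers_ok = ssi[_ANSWER_COLS].isin(["lighter", "heavier"]).all(axis=1)
    bad.update(ssi.index[~answers_ok])
    point = table[table["condition"] == "point"]
    bad.update(point.index[point["point_g"].isna()])
    unknown = table.index[~table["condition"].isin(["point", "ssi"])]
    bad.update(unknown)
    if bad:
        rows = sorted(int(i) for i in bad)
        raise TrialTableValidationError(
            f"{len(rows)} invalid trial row(s): {rows[:20]}"
            + (" ..." if len(rows) > 20 else ""),
            rows=rows,
        )


def read_trial_table(path, validate: bool = True) -> pd.DataFrame:
    """Read and (by default) validate a trial table CSV."""
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"empty trial table file: {path}") from exc
    if table.empty:
        raise EmptyInputError(f"trial table has no rows: {path}")
    if validate:
        validate_trial_table(table)
    table["session"] = table["session"].astype(int)
    table["trial_index"] = table["trial_index"].astype(int)
    return table[TRIAL_COLUMNS]
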