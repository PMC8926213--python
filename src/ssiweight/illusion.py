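"""Size-weight-illusion (SWI) quantification.

An SWI-case is a within-session comparison in which the smaller of two
equal-weight boxes of adjacent sizes is judged strictly heavier than the
larger one.  The SWI-factor is the signed proportional difference between
the two judgments, divided by the lighter of them, so +0.25 reads "the
smaller box was judged 25% heavier".  Interval non-overlap counts the
stronger finding that a respondent's first interval for the smaller box lies
entirely above the one for the larger box.

Judgments enter these metrics via a *measure*: the point judgment itself, or
the first/final interval midpoint (mid1/mid4) when the interval condition is
compared against the point condition.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ssiweight.design import StudyDesign, comparison_pairs
from ssiweight.exceptions import (
    EmptyInputError,
    InvalidInputError,
    MissingTrialWarning,
)

MEASURES = ("point", "mid1", "mid4")

#: trial-table column and condition that carry each measure
_MEASURE_SOURCE = {
    "point": ("point", "point_g"),
    "mid1": ("ssi", "mid1"),
    "mid4": ("ssi", "mid4"),
}

DEFAULT_OUTLIER_LIMIT = 10.0


def judgment_for_measure(row: pd.Series, measure: str) -> float:
    """Extract one judgment (g) from a trial row under the given measure."""
    condition, column = _measure_source(measure)
    if row["condition"] != condition:
        raise LookupError(
            f"measure {measure!r} needs a {condition!r} row, got {row['condition']!r}"
        )
    return float(row[column])


def _measure_source(measure: str) -> tuple[str, str]:
    try:
        return _MEASURE_SOURCE[measure]
    except KeyError:
        raise InvalidInputError(f"unknown measure {measure!r}") from None


def _judgment_lookup(table: pd.DataFrame, measure: str) -> pd.Series:
    """(participant, session, box) -> judgment for one measure."""
    condition, column = _measure_source(measure)
    sub = table[table["condition"] == condition]
    return sub.set_index(["participant_id", "session", "box_id"])[column]


def _pair_frame(
    table: pd.DataFrame,
    design: StudyDesign,
    lookup_s: pd.Series,
    lookup_l: pd.Series,
    measure_label: str,
) -> pd.DataFrame:
    """Long frame of within-session comparison pairs with both values attached.

    ``lookup_s``/``lookup_l`` map (participant, session, box) to the value
    compared for the smaller / larger box.  Pairs with a missing member are
    dropped with a warning; nothing is imputed.
    """
    pairs = comparison_pairs(design)
    participants = sorted(table["participant_id"].unique())
    sessions = sorted(table["session"].unique())
    records = []
    n_missing = 0
    for pid in participants:
        for session in sessions:
            for pair in pairs:
                key_s = (pid, session, pair.smaller_box_id)
                key_l = (pid, session, pair.larger_box_id)
                try:
                    v_s = lookup_s.loc[key_s]
                    v_l = lookup_l.loc[key_l]
                except KeyError:
                    n_missing += 1
                    continue
                if pd.isna(v_s) or pd.isna(v_l):
                    n_missing += 1
                    continue
                records.append(
                    {
                        "participant_id": pid,
                        "session": session,
                        "smaller_box_id": pair.smaller_box_id,
                        "larger_box_id": pair.larger_box_id,
                        "weight_g": pair.weight_g,
                        "measure": measure_label,
                        "smaller_value": float(v_s),
                        "larger_value": float(v_l),
                    }
                )
    if n_missing:
        warnings.warn(
            f"{n_missing} comparison pair(s) skipped for missing trials "
            f"({measure_label})",
            MissingTrialWarning,
            stacklevel=3,
        )
    return pd.DataFrame(records)


def comparison_frame(
    table: pd.DataFrame, design: StudyDesign, measure: str
) -> pd.DataFrame:
    """All within-session same-weight adjacent-size comparisons for a measure."""
    lookup = _judgment_lookup(table, measure)
    return _pair_frame(table, design, lookup, lookup, measure)


def count_swi_cases(
    table: pd.DataFrame, design: StudyDesign, measure: str
) -> pd.Series:
    """SWI-cases per participant: smaller box judged strictly heavier.

    Ties are non-cases.  In the default design the per-participant maximum
    is 8 pairs x 3 sessions = 24.
    """
    frame = comparison_frame(table, design, measure)
    if frame.empty:
        raise EmptyInputError("no comparison pairs found for measure " + measure)
    frame["case"] = frame["smaller_value"] > frame["larger_value"]
    counts = frame.groupby("participant_id")["case"].sum().astype(int)
    counts.name = f"swi_cases_{measure}"
    return counts


def count_nonoverlap(table: pd.DataFrame, design: StudyDesign) -> pd.Series:
    """Per participant: first-interval pairs where the smaller box's lower
    limit strictly exceeds the larger box's upper limit (no overlap)."""
    ssi = table[table["condition"] == "ssi"]
    if ssi.empty:
        raise EmptyInputError("no interval-condition rows in table")
    lower = ssi.set_index(["participant_id", "session", "box_id"])["l1"]
    upper = ssi.set_index(["participant_id", "session", "box_id"])["u1"]
    frame = _pair_frame(ssi, design, lower, upper, "nonoverlap")
    frame["case"] = frame["smaller_value"] > frame["larger_value"]
    counts = frame.groupby("participant_id")["case"].sum().astype(int)
    counts.name = "nonoverlap_cases"
    return counts


def swi_factor(j_smaller: float, j_larger: float) -> float:
    """Signed proportional judgment difference, divided by the lighter judgment."""
    if j_smaller <= 0 or j_larger <= 0:
        raise InvalidInputError("judgments must be positive")
    return (j_smaller - j_larger) / min(j_smaller, j_larger)


def swi_factor_records(
    table: pd.DataFrame,
    design: StudyDesign,
    measures: tuple[str, ...] = MEASURES,
) -> pd.DataFrame:
    """Long table of SWI-factors per participant x session x pair x measure."""
    frames = []
    for measure in measures:
        frame = comparison_frame(table, design, measure)
        frame["factor"] = (frame["smaller_value"] - frame["larger_value"]) / np.minimum(
            frame["smaller_value"], frame["larger_value"]
        )
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def filter_outliers(
    records: pd.DataFrame, limit: float = DEFAULT_OUTLIER_LIMIT
) -> pd.DataFrame:
    """Flag |factor| strictly greater than ``limit`` as excluded.

    A factor exactly at the limit is kept.  Returns a copy with an
    ``excluded`` column; exclusion counts per measure are available via
    ``frame.groupby('measure')['excluded'].sum()``.
    """
    if limit <= 0:
        raise InvalidInputError("outlier limit must be positive")
    out = records.copy()
    out["excluded"] = (out["factor"] > limit) | (out["factor"] < -limit)
    return out


def descriptive_table(values, integer_mode: bool = False) -> dict:
    """Min/Q1/Median/Q3/Max/Mean/SD summary of one value set.

    Quartiles use linear interpolation between order statistics; SD is the
    sample SD (n-1).  With ``integer_mode`` the mode (most frequent value,
    smallest on ties, flagged if multimodal) and its frequency are added.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise EmptyInputError("cannot summarize an empty value set")
    out = {
        "min": float(arr.min()),
        "q1": float(np.quantile(arr, 0.25, method="linear")),
        "median": float(np.quantile(arr, 0.5, method="linear")),
        "q3": float(np.quantile(arr, 0.75, method="linear")),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
    }
    if integer_mode:
        uniq, counts = np.unique(arr, return_counts=True)
        top = counts.max()
        modal = uniq[counts == top]
        out["mode"] = float(modal.min())
        out["mode_count"] = int(top)
        out["multimodal"] = bool(modal.size > 1)
    return out


def swi_case_summary(
    table: pd.DataFrame, design: StudyDesign, measures: tuple[str, ...] = MEASURES
) -> pd.DataFrame:
    """Cohort summary of SWI-cases per participant for each measure.

    Includes the sum of cases and its share of the total comparison count
    (sum / (participants x 24) in the default design).
    """
    total = len(comparison_pairs(design)) * design.n_sessions
    rows = {}
    for measure in measures:
        counts = count_swi_cases(table, design, measure)
        stats = descriptive_table(counts, integer_mode=True)
        stats["sum"] = int(counts.sum())
        stats["percent"] = 100.0 * counts.sum() / (total * counts.size)
        rows[measure] = stats
    return pd.DataFrame(rows).T


def swi_factor_summary(
    records: pd.DataFrame, limit: float = DEFAULT_OUTLIER_LIMIT
) -> pd.DataFrame:
    """Per-measure descriptives of SWI-factors, raw and outlier-filtered."""
    flagged = filter_outliers(records, limit)
    rows = []
    for filtered in (False, True):
        sub = flagged[~flagged["excluded"]] if filtered else flagged
        for measure, grp in sub.groupby("measure"):
            stats = descriptive_table(grp["factor"])
            stats["measure"] = measure
            stats["filtered"] = filtered
            stats["n_excluded"] = (
                int(flagged[flagged["measure"] == measure]["excluded"].sum())
                if filtered
                else 0
            )
            rows.append(stats)
    return pd.DataFrame(rows).set_index(["measure", "filtered"])
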