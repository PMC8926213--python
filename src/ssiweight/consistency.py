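"""Within-person consistency of judgments across sessions.

Each participant judges every box once per session; the consistency metric
is the relative standard deviation (coefficient of variation) of their three
judgments of one box — sample SD divided by their own mean.  Judging a box
as 350, 500 and 650 g gives SD 150 over mean 500, a relative SD of 0.3.
Relative SDs are computed per participant x box x measure, averaged over
boxes within each participant, and only then averaged across the cohort;
measures are compared with paired t-tests across participants.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ssiweight.exceptions import (
    EmptyInputError,
    InsufficientDataError,
    InvalidInputError,
    MissingTrialWarning,
)

#: measure -> (condition, column) series the relative SD is computed over
_MEASURE_COLUMNS = {
    "point": ("point", "point_g"),
    "mid1": ("ssi", "mid1"),
    "mid4": ("ssi", "mid4"),
    "lower_limit": ("ssi", "l1"),
    "upper_limit": ("ssi", "u1"),
}

DEFAULT_MEASURES = ("point", "mid1", "mid4")


def relative_sd(judgments) -> float:
    """Sample SD (n-1 denominator) of a judgment series divided by its mean."""
    arr = np.asarray(list(judgments), dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("relative SD needs at least 2 observations")
    mean = arr.mean()
    if mean <= 0:
        raise InvalidInputError("relative SD requires a positive mean")
    return float(arr.std(ddof=1) / mean)


def consistency_table(
    table: pd.DataFrame, measures: tuple[str, ...] = DEFAULT_MEASURES
) -> pd.DataFrame:
    """Relative SD per participant x box x measure over the sessions.

    Boxes with fewer than all sessions observed for a participant are
    excluded with a warning rather than imputed.
    """
    n_sessions = int(table["session"].nunique())
    if n_sessions < 2:
        raise InsufficientDataError("need at least 2 sessions for consistency")
    records = []
    n_skipped = 0
    for measure in measures:
        condition, column = _measure_columns(measure)
        sub = table[table["condition"] == condition]
        for (pid, box), grp in sub.groupby(["participant_id", "box_id"]):
            values = grp[column].dropna()
            if len(values) < n_sessions:
                n_skipped += 1
                continue
            records.append(
                {
                    "participant_id": pid,
                    "box_id": box,
                    "size_class": grp["size_class"].iloc[0],
                    "measure": measure,
                    "mean": float(values.mean()),
                    "sd": float(values.std(ddof=1)),
                    "relative_sd": relative_sd(values),
                }
            )
    if n_skipped:
        warnings.warn(
            f"{n_skipped} participant-box series skipped (incomplete sessions)",
            MissingTrialWarning,
            stacklevel=2,
        )
    if not records:
        raise EmptyInputError("no complete participant-box series")
    return pd.DataFrame(records)


def _measure_columns(measure: str) -> tuple[str, str]:
    try:
        return _MEASURE_COLUMNS[measure]
    except KeyError:
        raise InvalidInputError(f"unknown measure {measure!r}") from None


def participant_means(
    table: pd.DataFrame, measures: tuple[str, ...] = DEFAULT_MEASURES
) -> pd.DataFrame:
    """Each participant's mean relative SD over boxes, one column per measure."""
    frame = consistency_table(table, measures)
    return frame.pivot_table(
        index="participant_id", columns="measure", values="relative_sd",
        aggfunc="mean",
    )[list(measures)]


def consistency_summary(
    table: pd.DataFrame,
    measures: tuple[str, ...] = DEFAULT_MEASURES,
    pooled: bool = False,
) -> pd.DataFrame:
    """Cohort mean relative SD per measure plus paired comparisons vs point.

    Default aggregation is participant-first (mean over boxes within each
    participant, then cohort mean); ``pooled`` averages all participant-box
    relative SDs directly.  Paired two-tailed t-tests compare each midpoint
    measure against the point measure across participants; with zero
    variance in the differences the t statistic is reported as NaN.
    """
    per = participant_means(table, measures)
    if pooled:
        frame = consistency_table(table, measures)
        means = frame.groupby("measure")["relative_sd"].mean()
    else:
        means = per.mean()
    rows = []
    for measure in measures:
        row = {"measure": measure, "mean_relative_sd": float(means[measure])}
        if measure != "point" and "point" in per.columns:
            diff = per["point"] - per[measure]
            if np.allclose(diff.std(ddof=1), 0):
                row.update(t_stat=np.nan, p_value=np.nan, df=len(diff) - 1)
            else:
                t, p = stats.ttest_rel(per["point"], per[measure])
                row.update(t_stat=float(t), p_value=float(p), df=len(diff) - 1)
        rows.append(row)
    return pd.DataFrame(rows).set_index("measure")


def consistency_by_size(
    table: pd.DataFrame, measures: tuple[str, ...] = DEFAULT_MEASURES,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Mean relative SD by measure x size class with plain t-based CIs.

    CIs are ordinary between-participant t intervals (no within-subject
    correction), computed over per-participant means.
    """
    frame = consistency_table(table, measures)
    per = frame.groupby(["participant_id", "measure", "size_class"])[
        "relative_sd"
    ].mean().reset_index()
    rows = []
    for (measure, size), grp in per.groupby(["measure", "size_class"]):
        vals = grp["relative_sd"].to_numpy()
        mean = vals.mean()
        if vals.size > 1 and vals.std(ddof=1) > 0:
            half = stats.t.ppf(0.5 + confidence / 2, vals.size - 1) * stats.sem(vals)
        else:
            half = 0.0
        rows.append(
            {
                "measure": measure,
                "size_class": size,
                "mean_relative_sd": mean,
                "ci_low": mean - half,
                "ci_high": mean + half,
                "n": vals.size,
            }
        )
    return pd.DataFrame(rows).set_index(["measure", "size_class"])


def limit_variability(table: pd.DataFrame) -> pd.DataFrame:
    """Consistency of the raw interval limits (l1 and u1 series).

    Reports the cohort mean relative SD and mean absolute SD for the lower
    and upper limit judgments separately — upper limits typically vary more
    in grams simply because the numbers are larger, which is the argument
    for the relative measure.
    """
    frame = consistency_table(table, ("lower_limit", "upper_limit"))
    per_rel = frame.pivot_table(
        index="participant_id", columns="measure", values="relative_sd",
        aggfunc="mean",
    )
    per_abs = frame.pivot_table(
        index="participant_id", columns="measure", values="sd", aggfunc="mean",
    )
    return pd.DataFrame(
        {
            "mean_relative_sd": per_rel.mean(),
            "mean_absolute_sd_g": per_abs.mean(),
        }
    )
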