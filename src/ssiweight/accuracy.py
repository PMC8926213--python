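"""Accuracy of weight judgments.

The headline accuracy metric is the proportional absolute deviation,
``pad = |j/w - 1|``, where j is a judgment (point judgment or an interval
midpoint) and w the true weight — judging a 200 g box as 100 g or as 300 g
both give pad = 0.5.

Interval accuracy uses hits: the true weight lying STRICTLY inside a stated
interval.  Point coverage asks the different question of whether a
respondent's own point judgment falls INCLUSIVELY inside the interval they
gave for the same box in the same session of the other condition.  The
strict/inclusive asymmetry between the two definitions is deliberate and
preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ssiweight.engine import Interval
from ssiweight.exceptions import (
    DegenerateFitError,
    EmptyInputError,
    InvalidInputError,
)

MIDPOINT_MEASURES = ("mid1", "mid2", "mid3", "mid4")


def pad(judgment: float, true_weight: float) -> float:
    """Proportional absolute deviation |j/w - 1| of one judgment."""
    if true_weight <= 0:
        raise InvalidInputError("true weight must be positive")
    return abs(judgment / true_weight - 1.0)


def interval_hit(interval: Interval, true_weight: float) -> bool:
    """True weight strictly between the interval limits."""
    return interval.contains(true_weight, strict=True)


def point_covered(point: float, interval: Interval) -> bool:
    """Point judgment inclusively inside the interval (limits count as covered)."""
    return interval.contains(point, strict=False)


def pad_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-trial pad for every available measure, long format.

    Point rows yield measure 'point'; interval rows yield one record per
    midpoint measure mid1..mid4.
    """
    records = []
    point = table[table["condition"] == "point"]
    for _, row in point.iterrows():
        records.append(
            {
                "participant_id": row["participant_id"],
                "session": row["session"],
                "box_id": row["box_id"],
                "size_class": row["size_class"],
                "measure": "point",
                "judgment": row["point_g"],
                "true_weight_g": row["true_weight_g"],
                "pad": pad(row["point_g"], row["true_weight_g"]),
            }
        )
    ssi = table[table["condition"] == "ssi"]
    for _, row in ssi.iterrows():
        for measure in MIDPOINT_MEASURES:
            records.append(
                {
                    "participant_id": row["participant_id"],
                    "session": row["session"],
                    "box_id": row["box_id"],
                    "size_class": row["size_class"],
                    "measure": measure,
                    "judgment": row[measure],
                    "true_weight_g": row["true_weight_g"],
                    "pad": pad(row[measure], row["true_weight_g"]),
                }
            )
    return pd.DataFrame(records)


def mean_pad_by_measure(table: pd.DataFrame) -> pd.Series:
    """Cohort mean pad per measure (point, mid1..mid4), as proportions."""
    frame = pad_table(table)
    if frame.empty:
        raise EmptyInputError("no trials to compute pad from")
    return frame.groupby("measure")["pad"].mean()


def hit_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per interval-trial hit flags for splits 1-4 plus widths.

    Columns hit1..hit4 (strict containment of the true weight), width (first
    interval, g) and relative width (width / mid1).  Because the intervals
    are nested, a hit at split k+1 implies a hit at split k.
    """
    ssi = table[table["condition"] == "ssi"]
    if ssi.empty:
        raise EmptyInputError("no interval-condition rows in table")
    out = ssi[
        ["participant_id", "session", "box_id", "size_class", "true_weight_g"]
    ].copy()
    w = ssi["true_weight_g"]
    for k in range(1, 5):
        out[f"hit{k}"] = (ssi[f"l{k}"] < w) & (w < ssi[f"u{k}"])
    out["width"] = ssi["u1"] - ssi["l1"]
    out["relative_width"] = out["width"] / ssi["mid1"]
    return out


def hit_rates_by_split(
    table: pd.DataFrame,
    style: str = "pooled",
    by_size: bool = False,
) -> pd.DataFrame:
    """Hit rate at each split, pooled over trials or as mean of per-participant rates.

    ``style='pooled'`` divides total hits by total trials; ``'participant'``
    first computes each participant's rate then averages those.  With
    ``by_size`` rates are additionally grouped by box size class.
    """
    hits = hit_table(table)
    cols = [f"hit{k}" for k in range(1, 5)]
    if style == "pooled":
        grouped = hits.groupby("size_class")[cols].mean() if by_size else \
            hits[cols].mean().to_frame().T
    elif style == "participant":
        per = hits.groupby(
            ["participant_id", "size_class"] if by_size else "participant_id"
        )[cols].mean()
        grouped = per.groupby("size_class").mean() if by_size else \
            per.mean().to_frame().T
    else:
        raise InvalidInputError(f"unknown style {style!r}")
    grouped.columns = [f"split{k}" for k in range(1, 5)]
    if not by_size:
        grouped.index = ["rate"]
    return grouped


def coverage_table(table: pd.DataFrame) -> pd.DataFrame:
    """Match each point judgment with the same participant/session/box interval.

    The covered flag is inclusive: a point exactly on a limit counts as
    captured by the interval.
    """
    point = table[table["condition"] == "point"].set_index(
        ["participant_id", "session", "box_id"]
    )
    ssi = table[table["condition"] == "ssi"].set_index(
        ["participant_id", "session", "box_id"]
    )
    joined = point[["point_g"]].join(ssi[["l1", "u1"]], how="inner")
    if joined.empty:
        raise EmptyInputError("no matching point/interval trial pairs")
    joined["covered"] = (joined["l1"] <= joined["point_g"]) & (
        joined["point_g"] <= joined["u1"]
    )
    return joined.reset_index()


def coverage_by_participant(table: pd.DataFrame) -> pd.Series:
    """Proportion of each participant's point judgments captured by their intervals."""
    cov = coverage_table(table)
    return cov.groupby("participant_id")["covered"].mean()


def interval_widths(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial first-interval widths and per-participant means.

    Returns ``(per_trial, per_participant)``; widths in grams, relative
    width is width / mid1 (dimensionless, scale-invariant).
    """
    ssi = table[table["condition"] == "ssi"]
    if ssi.empty:
        raise EmptyInputError("no interval-condition rows in table")
    per_trial = ssi[["participant_id", "session", "box_id"]].copy()
    per_trial["width"] = ssi["u1"] - ssi["l1"]
    per_trial["relative_width"] = per_trial["width"] / ssi["mid1"]
    per_participant = per_trial.groupby("participant_id")[
        ["width", "relative_width"]
    ].mean()
    return per_trial, per_participant


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    p_value: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    t_stat: float
    p_value: float
    n: int


def simple_regression(y, x) -> RegressionResult:
    """Ordinary least squares of y on one predictor x.

    R^2 is the squared correlation; the F statistic (1, n-2 df) and its
    p-value test the slope against zero.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size != x.size or y.size < 3:
        raise DegenerateFitError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise DegenerateFitError("constant predictor")
    fit = stats.linregress(x, y)
    n = int(y.size)
    r2 = fit.rvalue**2
    if r2 >= 1.0:
        f = np.inf
        p = 0.0
    else:
        f = r2 / (1 - r2) * (n - 2)
        p = float(stats.f.sf(f, 1, n - 2))
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(r2),
        f_stat=float(f),
        p_value=p,
        n=n,
    )


def pearson_correlation(a, b, confidence: float = 0.95) -> CorrelationResult:
    """Product-moment correlation with a Fisher-z confidence interval."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise DegenerateFitError("need at least 3 paired observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateFitError("constant input")
    r, p = stats.pearsonr(a, b)
    n = int(a.size)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.5 + confidence / 2)
    lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    t = r * np.sqrt((n - 2) / (1 - r**2)) if abs(r) < 1 else np.inf
    return CorrelationResult(
        r=float(r), ci_low=float(lo), ci_high=float(hi),
        t_stat=float(t), p_value=float(p), n=n,
    )


def hit_width_correlation(table: pd.DataFrame) -> CorrelationResult:
    """Correlation of per-participant hit percentage with mean interval width."""
    hits = hit_table(table)
    per_hit = hits.groupby("participant_id")["hit1"].mean()
    _, per_width = interval_widths(table)
    joined = pd.concat([per_hit, per_width["width"]], axis=1).dropna()
    return pearson_correlation(joined["hit1"], joined["width"])
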