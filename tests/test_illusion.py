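"""SWI metrics: case counting, non-overlap, SWI-factor, descriptives."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ssiweight as sw
from ssiweight.design import comparison_pairs, with_participants
from ssiweight.exceptions import EmptyInputError, InvalidInputError
from ssiweight.illusion import (
    MEASURES,
    count_nonoverlap,
    count_swi_cases,
    descriptive_table,
    filter_outliers,
    judgment_for_measure,
    swi_case_summary,
    swi_factor,
    swi_factor_records,
    swi_factor_summary,
)
from ssiweight.simulate import TRIAL_COLUMNS


def build_table(design, point=None, intervals=None, participants=("P1",)):
    """Hand-build a trial table from per-(participant, session, box) values.

    ``point`` maps (pid, session, box_id) -> judgment; ``intervals`` maps the
    same keys -> (l1, u1).  Midpoints/l4/u4 mirror l1/u1 (metrics under test
    only read l1/u1/mid1/mid4/point_g).
    """
    rows = []
    for pid in participants:
        for session in range(1, design.n_sessions + 1):
            for i, box in enumerate(design.boxes, start=1):
                key = (pid, session, box.box_id)
                base = {c: np.nan for c in TRIAL_COLUMNS}
                base.update(
                    participant_id=pid, session=session, trial_index=i,
                    box_id=box.box_id, size_class=box.size_class,
                    true_weight_g=box.weight_g,
                )
                if point and key in point:
                    row = dict(base, condition="point", point_g=point[key])
                    rows.append(row)
                if intervals and key in intervals:
                    lo, up = intervals[key]
                    mid = (lo + up) / 2
                    row = dict(base, condition="ssi", l1=lo, u1=up,
                               mid1=mid, l4=lo, u4=up, mid4=mid)
                    rows.append(row)
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def oracle_swi_count(table, design, measure):
    """Exhaustive pairwise enumeration, independent of the implementation."""
    col = {"point": "point_g", "mid1": "mid1", "mid4": "mid4"}[measure]
    cond = "point" if measure == "point" else "ssi"
    sub = table[table["condition"] == cond]
    counts = {}
    for pid in sub["participant_id"].unique():
        n = 0
        for session in sub["session"].unique():
            for a, b in itertools.combinations(
                sub[(sub["participant_id"] == pid) & (sub["session"] == session)]
                .to_dict("records"),
                2,
            ):
                sizes = {"small": 0, "medium": 1, "large": 2}
                sa, sb = sizes[a["size_class"]], sizes[b["size_class"]]
                if a["true_weight_g"] != b["true_weight_g"] or abs(sa - sb) != 1:
                    continue
                smaller, larger = (a, b) if sa < sb else (b, a)
                if smaller[col] > larger[col]:
                    n += 1
        counts[pid] = n
    return counts


class TestSWIFactor:
    def test_published_examples(self):
        assert swi_factor(500, 400) == pytest.approx(0.25)
        assert swi_factor(400, 500) == pytest.approx(-0.25)

    def test_equal_judgments_give_zero(self):
        assert swi_factor(700, 700) == 0

    def test_nonpositive_judgment_rejected(self):
        with pytest.raises(InvalidInputError):
            swi_factor(0, 400)
        with pytest.raises(InvalidInputError):
            swi_factor(500, -1)

    @given(
        a=st.floats(min_value=1, max_value=1e5),
        b=st.floats(min_value=1, max_value=1e5),
    )
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry(self, a, b):
        assert swi_factor(a, b) == pytest.approx(-swi_factor(b, a))


class TestCountSWICases:
    def test_all_ties_count_zero(self, default_design):
        design = with_participants(default_design, 1)
        point = {
            ("P1", s, b.box_id): 500.0
            for s in (1, 2, 3)
            for b in design.boxes
        }
        table = build_table(design, point=point)
        assert count_swi_cases(table, design, "point")["P1"] == 0

    def test_smaller_always_heavier_hits_maximum(self, default_design):
        design = with_participants(default_design, 1)
        rank = {"small": 3, "medium": 2, "large": 1}
        point = {
            ("P1", s, b.box_id): b.weight_g * rank[b.size_class]
            for s in (1, 2, 3)
            for b in design.boxes
        }
        table = build_table(design, point=point)
        assert count_swi_cases(table, design, "point")["P1"] == 24

    def test_single_session_single_case(self, default_design):
        from ssiweight.design import StudyDesign

        design = StudyDesign(boxes=default_design.boxes, n_sessions=1,
                             n_participants=1)
        point = {("P1", 1, b.box_id): 500.0 for b in design.boxes}
        point[("P1", 1, "S3")] = 500.0  # small 455 g box
        point[("P1", 1, "M3")] = 400.0  # medium 455 g box judged lighter
        table = build_table(design, point=point)
        assert count_swi_cases(table, design, "point")["P1"] == 1

    def test_matches_exhaustive_oracle_on_simulated_data(self, small_table):
        design, table = small_table
        design = with_participants(design, 3)
        pids = sorted(table["participant_id"].unique())[:3]
        sub = table[table["participant_id"].isin(pids)]
        for measure in MEASURES:
            got = count_swi_cases(sub, design, measure)
            expected = oracle_swi_count(sub, design, measure)
            assert got.to_dict() == expected

    def test_missing_trial_skips_pair_with_warning(self, default_design):
        design = with_participants(default_design, 1)
        point = {
            ("P1", s, b.box_id): b.weight_g * {"small": 3, "medium": 2, "large": 1}[
                b.size_class
            ]
            for s in (1, 2, 3)
            for b in design.boxes
        }
        del point[("P1", 1, "S3")]  # lose one small box trial
        table = build_table(design, point=point)
        with pytest.warns(UserWarning, match="skipped"):
            counts = count_swi_cases(table, design, "point")
        assert counts["P1"] == 23


class TestNonOverlap:
    def test_disjoint_above_counts(self, default_design):
        design = with_participants(default_design, 1)
        intervals = {}
        for s in (1, 2, 3):
            for b in design.boxes:
                # smaller sizes get higher, non-overlapping ranges
                base = {"small": 500, "medium": 300, "large": 100}[b.size_class]
                intervals[("P1", s, b.box_id)] = (base, base + 100)
        table = build_table(design, intervals=intervals)
        assert count_nonoverlap(table, design)["P1"] == 24

    def test_overlapping_and_touching_do_not_count(self, default_design):
        design = with_participants(default_design, 1)
        intervals = {}
        for s in (1, 2, 3):
            for b in design.boxes:
                # smaller's lower == larger's upper: touching, not counted
                base = {"small": 300, "medium": 200, "large": 100}[b.size_class]
                intervals[("P1", s, b.box_id)] = (base, base + 100)
        table = build_table(design, intervals=intervals)
        assert count_nonoverlap(table, design)["P1"] == 0

    def test_no_ssi_rows_raises(self, default_design):
        design = with_participants(default_design, 1)
        point = {("P1", 1, b.box_id): 1.0 for b in design.boxes}
        table = build_table(design, point=point)
        with pytest.raises(EmptyInputError):
            count_nonoverlap(table, design)


class TestJudgmentForMeasure:
    def test_measures_read_their_columns(self, small_table):
        _, table = small_table
        ssi_row = table[table["condition"] == "ssi"].iloc[0]
        point_row = table[table["condition"] == "point"].iloc[0]
        assert judgment_for_measure(ssi_row, "mid1") == ssi_row["mid1"]
        assert judgment_for_measure(ssi_row, "mid4") == ssi_row["mid4"]
        assert judgment_for_measure(point_row, "point") == point_row["point_g"]

    def test_condition_mismatch_raises(self, small_table):
        _, table = small_table
        point_row = table[table["condition"] == "point"].iloc[0]
        with pytest.raises(LookupError):
            judgment_for_measure(point_row, "mid1")


class TestOutlierFilter:
    def test_strict_limit_behaviour(self):
        records = pd.DataFrame(
            {"measure": ["point"] * 4, "factor": [49.0, 10.0, -4.03, -10.5]}
        )
        flagged = filter_outliers(records, limit=10)
        assert flagged["excluded"].tolist() == [True, False, False, True]

    def test_summary_reports_exclusions(self):
        records = pd.DataFrame(
            {"measure": ["point"] * 3 + ["mid1"] * 3,
             "factor": [49.0, 0.5, 1.0, -11.0, 0.2, 0.3]}
        )
        summary = swi_factor_summary(records)
        assert summary.loc[("point", True), "n_excluded"] == 1
        assert summary.loc[("mid1", True), "n_excluded"] == 1
        assert summary.loc[("point", False), "max"] == 49.0
        assert summary.loc[("point", True), "max"] == 1.0


class TestDescriptiveTable:
    def test_quartiles_linear_interpolation(self):
        stats = descriptive_table([1, 2, 3, 4, 5])
        assert stats["median"] == 3
        assert stats["q1"] == 2
        assert stats["q3"] == 4

    def test_constant_values_have_zero_sd(self):
        assert descriptive_table([7, 7, 7])["sd"] == 0

    def test_published_sd_example(self):
        # three session judgments 350/500/650 g: mean 500, sample SD 150
        stats = descriptive_table([350, 500, 650])
        assert stats["mean"] == 500
        assert stats["sd"] == pytest.approx(150)

    def test_mode_smallest_on_ties(self):
        stats = descriptive_table([1, 1, 2, 2, 3], integer_mode=True)
        assert stats["mode"] == 1
        assert stats["mode_count"] == 2
        assert stats["multimodal"]

    def test_empty_input_raises(self):
        with pytest.raises(EmptyInputError):
            descriptive_table([])


class TestSummaries:
    def test_percent_arithmetic_on_default_design(self, small_table):
        design, table = small_table
        summary = swi_case_summary(table, design)
        total = 24 * table["participant_id"].nunique()
        for measure in MEASURES:
            assert summary.loc[measure, "percent"] == pytest.approx(
                100 * summary.loc[measure, "sum"] / total
            )
            assert 0 <= summary.loc[measure, "max"] <= 24

    def test_factor_records_have_24_per_participant_measure(self, small_table):
        design, table = small_table
        records = swi_factor_records(table, design)
        counts = records.groupby(["participant_id", "measure"]).size()
        assert (counts == 24).all()


class TestBiasRecovery:
    def test_mean_swi_factor_increases_with_bias_ratio(self, default_design):
        """Stronger simulated illusion => larger mean SWI-factor."""
        design = with_participants(default_design, 8)
        means = []
        for bias_small, bias_large in [(1.1, 0.9), (1.4, 0.7), (1.8, 0.55)]:
            base = sw.RespondentModel(
                bias_by_size={"small": bias_small, "medium": 1.0,
                              "large": bias_large},
            )
            models = sw.make_cohort(8, master_seed=77, base=base, jitter=False)
            table = sw.simulate_study(design, models, master_seed=77)
            records = swi_factor_records(table, design)
            kept = filter_outliers(records)
            means.append(kept[~kept["excluded"]]["factor"].mean())
        assert means[0] < means[1] < means[2]

    def test_no_bias_no_noise_counts_zero(self, default_design):
        """Equal judgments never fire the strict inequality."""
        design = with_participants(default_design, 2)
        base = sw.RespondentModel(
            bias_by_size={"small": 1 + 1e-12, "medium": 1.0, "large": 1 - 1e-12},
            noise_cv=0.0,
        )
        models = sw.make_cohort(2, master_seed=1, base=base, jitter=False)
        table = sw.simulate_study(design, models, master_seed=1,
                                  conditions=("point",))
        counts = count_swi_cases(table, design, "point")
        assert (counts == 0).all()
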