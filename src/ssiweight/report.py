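"""End-to-end orchestration: simulate, analyze, and write the report bundle.

``run_analyze`` turns one trial table into the full set of metric CSVs plus
a markdown summary laid out like the study's reporting order: illusion
first, then accuracy, then consistency.  ``run_reproduce`` chains the
simulator in front of it.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ssiweight import accuracy, consistency, illusion
from ssiweight.design import StudyDesign, build_default_design, with_participants
from ssiweight.exceptions import ConfigurationError
from ssiweight.io import write_trial_table
from ssiweight.simulate import RespondentModel, make_cohort, simulate_study

log = logging.getLogger("ssiweight")


@dataclass
class RunConfig:
    """Configuration of one reproduce/simulate run."""

    seed: int
    n_participants: int = 31
    out_dir: Path = Path("ssiweight_out")
    mode: str = "perceptual"
    outlier_limit: float = 10.0
    pooled_cv: bool = False
    base_model: RespondentModel | None = None
    design: StudyDesign | None = None
    jitter: bool = True
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("need at least one participant")
        self.out_dir = Path(self.out_dir)


def run_simulate(config: RunConfig) -> pd.DataFrame:
    """Generate the synthetic trial table for the configured cohort."""
    design = config.design or build_default_design()
    design = with_participants(design, config.n_participants)
    models = make_cohort(
        config.n_participants,
        master_seed=config.seed,
        mode=config.mode,  # type: ignore[arg-type]
        base=config.base_model,
        jitter=config.jitter,
    )
    log.info(
        "simulating %d participants (mode=%s, seed=%d)",
        config.n_participants, config.mode, config.seed,
    )
    return simulate_study(design, models, master_seed=config.seed)


def run_analyze(
    table: pd.DataFrame, config: RunConfig, design: StudyDesign | None = None
) -> dict[str, Path]:
    """Compute every metric table from one trial table and write the bundle."""
    design = design or config.design or build_default_design()
    n_participants = table["participant_id"].nunique()
    design = with_participants(design, n_participants)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame, index: bool = True) -> None:
        path = out / f"{name}.csv"
        frame.to_csv(path, index=index)
        written[name] = path
        log.info("wrote %s", path)

    # --- illusion ---------------------------------------------------------
    swi_cases = pd.DataFrame(
        {m: illusion.count_swi_cases(table, design, m) for m in illusion.MEASURES}
    )
    emit("swi_cases", swi_cases)
    emit("swi_case_summary", illusion.swi_case_summary(table, design))
    emit("nonoverlap", illusion.count_nonoverlap(table, design).to_frame())
    factors = illusion.filter_outliers(
        illusion.swi_factor_records(table, design), config.outlier_limit
    )
    emit("swi_factors", factors, index=False)
    emit("swi_factor_summary",
         illusion.swi_factor_summary(factors, config.outlier_limit))

    # --- accuracy ---------------------------------------------------------
    emit("accuracy", accuracy.pad_table(table), index=False)
    mean_pad = accuracy.mean_pad_by_measure(table).to_frame("mean_pad")
    emit("mean_pad", mean_pad)
    hits = accuracy.hit_table(table)
    emit("hits", hits, index=False)
    rates_pooled = accuracy.hit_rates_by_split(table, style="pooled")
    rates_part = accuracy.hit_rates_by_split(table, style="participant")
    rates_size = accuracy.hit_rates_by_split(table, style="pooled", by_size=True)
    emit("hit_rates", pd.concat(
        {"pooled": rates_pooled, "participant_mean": rates_part}, names=["style"]
    ))
    emit("hit_rates_by_size", rates_size)
    emit("coverage", accuracy.coverage_table(table), index=False)
    _, widths = accuracy.interval_widths(table)
    emit("interval_widths", widths)

    # --- consistency ------------------------------------------------------
    emit("consistency", consistency.consistency_table(table), index=False)
    summary_cv = consistency.consistency_summary(table, pooled=config.pooled_cv)
    emit("consistency_summary", summary_cv)
    emit("consistency_by_size", consistency.consistency_by_size(table))
    emit("limit_variability", consistency.limit_variability(table))

    _write_summary_md(out / "summary.md", table, design, config, written,
                      swi_cases, factors, mean_pad, rates_pooled, summary_cv)
    written["summary"] = out / "summary.md"
    return written


def run_reproduce(config: RunConfig) -> dict[str, Path]:
    """Simulate the full synthetic study, analyze it, and write all tables."""
    table = run_simulate(config)
    config.out_dir.mkdir(parents=True, exist_ok=True)
    trials_path = config.out_dir / "trials.csv"
    write_trial_table(table, trials_path)
    log.info("wrote %s (%d rows)", trials_path, len(table))
    written = run_analyze(table, config)
    written["trials"] = trials_path
    return written


def _write_summary_md(
    path: Path,
    table: pd.DataFrame,
    design: StudyDesign,
    config: RunConfig,
    written: dict[str, Path],
    swi_cases: pd.DataFrame,
    factors: pd.DataFrame,
    mean_pad: pd.DataFrame,
    rates_pooled: pd.DataFrame,
    summary_cv: pd.DataFrame,
) -> None:
    from ssiweight.design import comparison_pairs, total_comparisons

    n_part = table["participant_id"].nunique()
    total = total_comparisons(design, per_condition=True)
    kept = factors[~factors["excluded"]]
    cov = accuracy.coverage_by_participant(table)
    lines = [
        "# Synthetic study report",
        "",
        f"Participants: {n_part}; sessions: {design.n_sessions}; "
        f"boxes: {len(design.boxes)}; seed: {config.seed}; mode: {config.mode}",
        f"Comparison pairs per session: {len(comparison_pairs(design))}; "
        f"total comparisons per condition: {total}",
        "",
        "## Size-weight illusion",
        "",
        "Mean SWI-cases per participant (max "
        f"{total_comparisons(design)}): "
        + ", ".join(f"{m} {swi_cases[m].mean():.2f}" for m in swi_cases.columns),
        f"SWI-cases as % of all comparisons: "
        + ", ".join(
            f"{m} {100 * swi_cases[m].sum() / total:.1f}%" for m in swi_cases.columns
        ),
        "",
        "Median SWI-factor (outliers beyond "
        f"+/-{config.outlier_limit:g} removed): "
        + ", ".join(
            f"{m} {kept[kept['measure'] == m]['factor'].median():.2f}"
            for m in illusion.MEASURES
        ),
        "",
        "## Accuracy",
        "",
        "Mean proportional absolute deviation (pad): "
        + ", ".join(
            f"{m} {100 * mean_pad.loc[m, 'mean_pad']:.1f}%" for m in mean_pad.index
        ),
        "Interval hit rate per split (pooled): "
        + ", ".join(
            f"split {k} {100 * rates_pooled.iloc[0][f'split{k}']:.1f}%"
            for k in range(1, 5)
        ),
        f"Point judgments captured by own interval: {100 * cov.mean():.1f}% "
        f"(participant mean)",
        "",
        "## Consistency",
        "",
        "Mean relative SD: "
        + ", ".join(
            f"{m} {summary_cv.loc[m, 'mean_relative_sd']:.3f}"
            for m in summary_cv.index
        ),
        "",
        "## Files",
        "",
    ]
    lines += [f"- `{p.name}`" for p in written.values()]
    lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")
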