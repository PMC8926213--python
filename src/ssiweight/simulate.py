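"""Synthetic respondents for the weight-judgment study.

The perceptual observer forms an internal estimate of a box's weight as
``true_weight x size_bias x exp(eps)``: a size-dependent multiplicative bias
(smaller boxes of equal weight feel heavier, the size-weight illusion) and
multiplicative log-normal noise.  Point judgments report that estimate,
rounded to a grams granularity.  Interval judgments place a relative
half-width around the estimate and answer each bisection probe by comparing
a fresh internal draw with the probe value, so split answers are informative
but imperfect.

The random responder is the null observer behind the chance baselines:
judgments are iid uniform draws and probe answers are fair coins, giving
12/24 expected illusion cases and interval hit rates that halve per split.

None of the perceptual parameters are estimates of the study's participants;
they are stand-ins that reproduce the qualitative structure the analysis
assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ssiweight.design import SIZE_CLASSES, BoxSpec, StudyDesign
from ssiweight.engine import (
    HEAVIER,
    LIGHTER,
    Interval,
    ProbeRounding,
    SSITrial,
    run_splitting,
)
from ssiweight.exceptions import ConfigurationError, InvalidInputError

Mode = Literal["perceptual", "random"]

#: Default size-bias multipliers: equal-weight smaller boxes feel heavier.
DEFAULT_BIAS = {"small": 1.4, "medium": 1.0, "large": 0.7}
DEFAULT_NOISE_CV = 0.25
DEFAULT_INTERVAL_HALFWIDTH = 0.30
DEFAULT_POINT_ROUNDING_G = 5.0
DEFAULT_RANDOM_RANGE = (50.0, 5000.0)

#: TrialTable column order; the interchange schema of the whole pipeline.
TRIAL_COLUMNS = [
    "participant_id",
    "condition",
    "session",
    "trial_index",
    "box_id",
    "size_class",
    "true_weight_g",
    "point_g",
    "l1", "u1", "a1",
    "l2", "u2", "a2",
    "l3", "u3", "a3",
    "l4", "u4",
    "mid1", "mid2", "mid3", "mid4",
]


@dataclass(frozen=True)
class RespondentModel:
    """Parameter set of one synthetic observer.

    ``bias_by_size`` must be strictly decreasing small > medium > large in
    perceptual mode (the illusion's direction); ``noise_cv`` is the
    coefficient of variation of the multiplicative log-normal noise;
    ``interval_halfwidth`` is the relative half-width u of the initial
    interval [e/(1+u), e*(1+u)] around the internal estimate e.
    """

    bias_by_size: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BIAS))
    noise_cv: float = DEFAULT_NOISE_CV
    interval_halfwidth: float = DEFAULT_INTERVAL_HALFWIDTH
    point_rounding_g: float = DEFAULT_POINT_ROUNDING_G
    mode: Mode = "perceptual"
    seed: int = 0
    frozen_percept: bool = False
    random_range: tuple[float, float] = DEFAULT_RANDOM_RANGE

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise InvalidInputError("noise_cv must be >= 0")
        if self.interval_halfwidth <= 0:
            raise InvalidInputError("interval_halfwidth must be > 0")
        if self.point_rounding_g <= 0:
            raise InvalidInputError("point_rounding_g must be > 0")
        if self.mode == "perceptual":
            b = self.bias_by_size
            if set(b) != set(SIZE_CLASSES):
                raise InvalidInputError("bias_by_size needs small/medium/large keys")
            if not all(v > 0 for v in b.values()):
                raise InvalidInputError("bias multipliers must be positive")
            if not (b["small"] > b["medium"] > b["large"]):
                raise InvalidInputError(
                    "perceptual mode requires strictly decreasing bias with size"
                )
        elif self.mode != "random":
            raise InvalidInputError(f"unknown mode {self.mode!r}")
        lo, hi = self.random_range
        if not 0 <= lo < hi:
            raise InvalidInputError("random_range must be ordered and non-negative")


def _log_sigma(noise_cv: float) -> float:
    # CV of exp(eps), eps ~ N(0, s^2), is sqrt(exp(s^2) - 1)
    return math.sqrt(math.log1p(noise_cv**2))


def sample_internal_estimate(
    model: RespondentModel, box: BoxSpec, rng: np.random.Generator
) -> float:
    """One fresh internal weight estimate (g) of the perceptual observer."""
    if model.mode != "perceptual":
        raise InvalidInputError(
            "internal estimates are defined only for the perceptual observer"
        )
    bias = model.bias_by_size[box.size_class]
    if model.noise_cv == 0:
        return box.weight_g * bias
    eps = rng.normal(0.0, _log_sigma(model.noise_cv))
    return box.weight_g * bias * math.exp(eps)


def _round_to(value: float, granularity: float) -> float:
    return round(value / granularity) * granularity


def make_point_trial(
    model: RespondentModel, box: BoxSpec, rng: np.random.Generator
) -> float:
    """One point judgment (g): rounded internal estimate, or a uniform draw."""
    if model.mode == "perceptual":
        estimate = sample_internal_estimate(model, box, rng)
    else:
        estimate = rng.uniform(*model.random_range)
    return _round_to(estimate, model.point_rounding_g)


def make_ssi_trial(
    model: RespondentModel,
    box: BoxSpec,
    rng: np.random.Generator,
    rounding: ProbeRounding = "half-even",
) -> SSITrial:
    """One full interval trial: initial interval plus three probe answers.

    Perceptual mode centres the initial interval on one internal draw e,
    bounds rounded outward to whole grams (so width stays >= 1 g), and
    answers each probe 'heavier' iff a fresh internal draw exceeds it
    (``frozen_percept`` reuses e instead).  Random mode draws two ordered
    uniform bounds and answers probes by fair coin.
    """
    if model.mode == "perceptual":
        e = sample_internal_estimate(model, box, rng)
        u = model.interval_halfwidth
        lower = math.floor(e / (1 + u))
        upper = math.ceil(e * (1 + u))
        if model.frozen_percept:
            answer_source = lambda probe: HEAVIER if e > probe else LIGHTER  # noqa: E731
        else:
            def answer_source(probe: float) -> str:
                draw = sample_internal_estimate(model, box, rng)
                return HEAVIER if draw > probe else LIGHTER
    else:
        a, b = sorted(rng.uniform(*model.random_range, size=2))
        lower, upper = math.floor(a), math.ceil(b)
        answer_source = lambda probe: HEAVIER if rng.random() < 0.5 else LIGHTER  # noqa: E731
    if upper <= lower:  # degenerate draw; outward rounding floor
        upper = lower + 1
    trial = run_splitting(Interval(float(lower), float(upper)), answer_source,
                          rounding=rounding)
    return replace(trial, box_id=box.box_id)


def make_cohort(
    n: int,
    master_seed: int,
    mode: Mode = "perceptual",
    base: RespondentModel | None = None,
    jitter: bool = True,
) -> list[RespondentModel]:
    """Build ``n`` respondent models with heterogeneous parameters.

    Heterogeneity emulates the individual variability seen in interval
    studies — some respondents keep narrow intervals throughout, others
    widen them with the judged magnitude.  Illusion strength is jittered as
    a log-normal exponent on the size biases, which preserves the
    small > medium > large ordering for every respondent.
    """
    base = base or RespondentModel(mode=mode)
    # dedicated sub-stream so cohort jitter never collides with trial streams
    rng = np.random.default_rng(np.random.SeedSequence([master_seed, 791992]))
    models = []
    for i in range(n):
        if mode == "random" or not jitter:
            models.append(replace(base, mode=mode, seed=i))
            continue
        strength = rng.lognormal(0.0, 0.3)
        bias = {
            "small": base.bias_by_size["small"] ** strength,
            "medium": 1.0,
            "large": base.bias_by_size["large"] ** strength,
        }
        halfwidth = float(np.clip(base.interval_halfwidth * rng.lognormal(0.0, 0.5),
                                  0.05, 1.0))
        noise_cv = float(base.noise_cv * rng.lognormal(0.0, 0.3))
        models.append(
            replace(base, bias_by_size=bias, interval_halfwidth=halfwidth,
                    noise_cv=noise_cv, seed=i)
        )
    return models


def _blank_row() -> dict:
    return {c: np.nan for c in TRIAL_COLUMNS}


def simulate_participant(
    design: StudyDesign,
    model: RespondentModel,
    participant_id: str,
    master_seed: int,
    conditions: Sequence[str] = ("point", "ssi"),
) -> list[dict]:
    """All trials of one participant; reproducible in isolation.

    The participant's random stream is derived from (master_seed,
    model.seed), so regenerating a single participant yields the same rows
    as a full-cohort run.
    """
    rng = np.random.default_rng(np.random.SeedSequence([master_seed, model.seed]))
    rows = []
    for condition in conditions:
        for session in range(1, design.n_sessions + 1):
            sequence = design.sequences[session - 1] if design.sequences else [
                b.box_id for b in design.boxes
            ]
            for trial_index, box_id in enumerate(sequence, start=1):
                box = design.box(box_id)
                row = _blank_row()
                row.update(
                    participant_id=participant_id,
                    condition=condition,
                    session=session,
                    trial_index=trial_index,
                    box_id=box_id,
                    size_class=box.size_class,
                    true_weight_g=box.weight_g,
                )
                if condition == "point":
                    row["point_g"] = make_point_trial(model, box, rng)
                else:
                    trial = make_ssi_trial(model, box, rng)
                    for k, iv in enumerate(trial.intervals, start=1):
                        row[f"l{k}"] = iv.lower_g
                        row[f"u{k}"] = iv.upper_g
                        row[f"mid{k}"] = iv.midpoint
                    for k, ans in enumerate(trial.answers, start=1):
                        row[f"a{k}"] = ans
                rows.append(row)
    return rows


def simulate_study(
    design: StudyDesign,
    models: Sequence[RespondentModel],
    master_seed: int,
    conditions: Sequence[str] = ("point", "ssi"),
) -> pd.DataFrame:
    """Simulate the full factorial study into a long-format trial table.

    One row per participant x condition x session x box: the default design
    with 31 respondents gives 31 x 2 x 3 x 15 = 2790 rows, half of them
    interval trials.
    """
    if len(models) != design.n_participants:
        raise ConfigurationError(
            f"need one model per participant: {len(models)} models for "
            f"{design.n_participants} participants"
        )
    for c in conditions:
        if c not in ("point", "ssi"):
            raise ConfigurationError(f"unknown condition {c!r}")
    width = max(2, len(str(max(design.n_participants, 1))))
    rows: list[dict] = []
    for i, model in enumerate(models, start=1):
        pid = f"P{i:0{width}d}"
        rows.extend(
            simulate_participant(design, model, pid, master_seed, conditions)
        )
    table = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    table["session"] = table["session"].astype(int)
    table["trial_index"] = table["trial_index"].astype(int)
    return table
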