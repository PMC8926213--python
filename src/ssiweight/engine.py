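"""The self-selected interval (SSI) splitting procedure.

A respondent first states an initial interval [lower, upper] — the smallest
and largest weight the box could reasonably have.  The interval is then
bisected three times: at each step the respondent is asked whether the box is
lighter or heavier than the (integer-rounded) midpoint, and the answer keeps
the lower or upper half.  The arithmetic midpoint of the fourth, final
interval is taken as the respondent's best estimate; it is never reported
explicitly by the respondent.

Probes shown to the respondent are rounded to a whole number of grams using
round-half-to-even by default (e.g. the midpoint 162.5 of [150, 175] is
probed as 162); the recorded interval endpoints use the rounded probe, while
stored midpoints (``mid1``..``mid4``) are exact, unrounded means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

from ssiweight.exceptions import (
    DegenerateIntervalError,
    IncompleteTrialError,
    InconsistentProbeError,
    InvalidInputError,
)

LIGHTER = "lighter"
HEAVIER = "heavier"
Answer = Literal["lighter", "heavier"]
ProbeRounding = Literal["half-even", "half-down", "none"]

DEFAULT_N_SPLITS = 3


@dataclass(frozen=True)
class Interval:
    """A [lower, upper] gram range with positive width."""

    lower_g: float
    upper_g: float

    def __post_init__(self) -> None:
        if self.lower_g < 0 or self.upper_g < 0:
            raise InvalidInputError("interval bounds must be non-negative")
        if not self.upper_g > self.lower_g:
            raise DegenerateIntervalError(
                f"interval must have positive width, got [{self.lower_g}, {self.upper_g}]"
            )

    @property
    def width(self) -> float:
        return self.upper_g - self.lower_g

    @property
    def midpoint(self) -> float:
        return (self.lower_g + self.upper_g) / 2

    def contains(self, x: float, strict: bool = True) -> bool:
        if strict:
            return self.lower_g < x < self.upper_g
        return self.lower_g <= x <= self.upper_g


@dataclass(frozen=True)
class SSITrial:
    """One interval-condition trial: nested intervals, probe answers, midpoints.

    ``intervals`` holds the initial interval followed by one interval per
    split; ``answers`` has one entry per split.  Metadata fields are None for
    bare engine output and filled in by the simulator / elicitation CLI.
    """

    intervals: tuple[Interval, ...]
    answers: tuple[Answer, ...]
    participant_id: str | None = None
    session: int | None = None
    box_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.answers) + 1:
            raise IncompleteTrialError(
                "need exactly one more interval than answers"
            )

    @property
    def mids(self) -> tuple[float, ...]:
        """Exact (unrounded) arithmetic midpoints of each interval."""
        return tuple(iv.midpoint for iv in self.intervals)


def make_initial_interval(lower: float, upper: float) -> Interval:
    """Validate and build the respondent's initial interval."""
    if lower < 0 or upper < 0:
        raise InvalidInputError("interval bounds must be non-negative")
    if upper <= lower:
        raise DegenerateIntervalError(
            f"upper bound must exceed lower bound, got [{lower}, {upper}]"
        )
    return Interval(lower, upper)


def round_probe(value: float, rounding: ProbeRounding = "half-even") -> float:
    """Round a midpoint to the integer gram value shown to the respondent."""
    if rounding == "none":
        return value
    if rounding == "half-even":
        return float(round(value))
    if rounding == "half-down":
        return float(math.ceil(value - 0.5))
    raise InvalidInputError(f"unknown probe rounding {rounding!r}")


def midpoint_probe(interval: Interval, rounding: ProbeRounding = "half-even") -> float:
    """The probe value for an interval: its arithmetic mean, integer-rounded.

    With integer bounds the mean is either whole or ends in .5, so only the
    .5 case invokes the tie rule; half-even and half-down both reproduce the
    published 162.5 -> 162 example.

    If no integer lies strictly inside the interval (width <= 1, where the
    rounded mean would collide with a bound), the exact midpoint is used so
    the procedure stays well defined on arbitrarily narrow intervals.
    """
    probe = round_probe(interval.midpoint, rounding)
    if not interval.lower_g < probe < interval.upper_g:
        return interval.midpoint
    return probe


def apply_answer(interval: Interval, probe: float, answer: Answer) -> Interval:
    """Keep the upper half on 'heavier', the lower half on 'lighter'."""
    if not interval.lower_g < probe < interval.upper_g:
        raise InconsistentProbeError(
            f"probe {probe} not strictly inside [{interval.lower_g}, {interval.upper_g}]"
        )
    if answer == HEAVIER:
        return Interval(probe, interval.upper_g)
    if answer == LIGHTER:
        return Interval(interval.lower_g, probe)
    raise InvalidInputError(f"answer must be {LIGHTER!r} or {HEAVIER!r}, got {answer!r}")


def run_splitting(
    initial: Interval,
    answer_source: Callable[[float], Answer] | Sequence[Answer],
    n_splits: int = DEFAULT_N_SPLITS,
    rounding: ProbeRounding = "half-even",
) -> SSITrial:
    """Run the bisection protocol from an initial interval.

    ``answer_source`` is either a callable mapping each probe (g) to an
    answer, or a pre-recorded sequence of answers of length ``n_splits``.
    Returns the trial fragment: the n_splits+1 nested intervals and the
    recorded answers.
    """
    if n_splits < 0:
        raise InvalidInputError("n_splits must be >= 0")
    if not callable(answer_source):
        recorded = list(answer_source)
        if len(recorded) != n_splits:
            raise InvalidInputError(
                f"need {n_splits} answers, got {len(recorded)}"
            )
        it = iter(recorded)
        answer_source = lambda probe: next(it)  # noqa: E731

    intervals = [initial]
    answers: list[Answer] = []
    current = initial
    for _ in range(n_splits):
        probe = midpoint_probe(current, rounding)
        answer = answer_source(probe)
        current = apply_answer(current, probe, answer)
        intervals.append(current)
        answers.append(answer)
    return SSITrial(intervals=tuple(intervals), answers=tuple(answers))


def best_estimate(trial: SSITrial, n_splits: int = DEFAULT_N_SPLITS) -> float:
    """Midpoint of the final interval — the respondent's inferred best guess.

    Exact arithmetic mean, never rounded.
    """
    if len(trial.intervals) != n_splits + 1:
        raise IncompleteTrialError(
            f"trial has {len(trial.intervals)} intervals, expected {n_splits + 1}"
        )
    return trial.intervals[-1].midpoint
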