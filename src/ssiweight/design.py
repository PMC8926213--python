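"""Stimulus set and experimental structure of the weight-judgment study.

The default design is 15 cardboard boxes in three sizes (small, medium,
large; five weights each), judged once per box in each of three sessions,
under two conditions (point judgments and self-selected intervals) by 31
participants.  Weights are chosen so that four weights are shared between
adjacent sizes, yielding the same-weight different-size comparison pairs on
which every size-weight-illusion metric is built.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from ssiweight.exceptions import ConfigurationError, InvalidInputError

SIZE_CLASSES = ("small", "medium", "large")
_SIZE_RANK = {s: i for i, s in enumerate(SIZE_CLASSES)}

#: Outer side length (cm) and height including lid (cm) per size class.
_DIMENSIONS = {
    "small": (6.8, 7.4),
    "medium": (12.3, 12.8),
    "large": (22.4, 22.8),
}

#: Box weights (g) per size class, ordered by overall weight rank.
_WEIGHTS = {
    "small": [(1, 114.0), (2, 235.0), (3, 455.0), (4, 649.0), (5, 1140.0)],
    "medium": [(2, 235.0), (3, 455.0), (4, 649.0), (5, 1140.0), (6, 2199.0)],
    "large": [(3, 455.0), (4, 649.0), (5, 1140.0), (6, 2199.0), (7, 3808.0)],
}

DEFAULT_SEQUENCE_SEED = 20220316
DEFAULT_N_SESSIONS = 3
DEFAULT_N_PARTICIPANTS = 31


@dataclass(frozen=True)
class BoxSpec:
    """One physical stimulus box."""

    box_id: str
    size_class: str
    side_cm: float
    height_cm: float
    weight_g: float
    weight_rank: int

    def __post_init__(self) -> None:
        if self.size_class not in SIZE_CLASSES:
            raise InvalidInputError(f"unknown size class {self.size_class!r}")
        if self.weight_g <= 0:
            raise InvalidInputError(f"weight must be positive, got {self.weight_g}")
        if self.side_cm <= 0 or self.height_cm <= 0:
            raise InvalidInputError("box dimensions must be positive")


@dataclass(frozen=True)
class ComparisonPair:
    """A same-weight pair of boxes of adjacent sizes (smaller vs one size larger)."""

    smaller_box_id: str
    larger_box_id: str
    weight_g: float


@dataclass(frozen=True)
class StudyDesign:
    """Box set plus session structure.

    ``sequences`` holds one box-id ordering per session; the same orderings
    are used in both judgment conditions.
    """

    boxes: tuple[BoxSpec, ...]
    n_sessions: int = DEFAULT_N_SESSIONS
    n_participants: int = DEFAULT_N_PARTICIPANTS
    sequences: tuple[tuple[str, ...], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_sessions < 1 or self.n_participants < 0:
            raise ConfigurationError("n_sessions must be >= 1 and n_participants >= 0")
        ids = {b.box_id for b in self.boxes}
        if len(ids) != len(self.boxes):
            raise ConfigurationError("duplicate box ids")
        if self.sequences:
            if len(self.sequences) != self.n_sessions:
                raise ConfigurationError("need one sequence per session")
            for seq in self.sequences:
                if sorted(seq) != sorted(ids):
                    raise ConfigurationError(
                        "each sequence must be a permutation of all box ids"
                    )

    def box(self, box_id: str) -> BoxSpec:
        for b in self.boxes:
            if b.box_id == box_id:
                return b
        raise KeyError(box_id)


def build_default_design(
    sequence_seed: int = DEFAULT_SEQUENCE_SEED,
    n_sessions: int = DEFAULT_N_SESSIONS,
    n_participants: int = DEFAULT_N_PARTICIPANTS,
) -> StudyDesign:
    """Return the 15-box default design with seeded session sequences.

    The published design does not fix the three box orderings, only that the
    15 boxes were permuted into three sequences reused across conditions;
    they are generated here by a seeded pseudo-random permutation so runs are
    reproducible.
    """
    boxes = []
    for size in SIZE_CLASSES:
        side, height = _DIMENSIONS[size]
        for rank, weight in _WEIGHTS[size]:
            box_id = f"{size[0].upper()}{rank}"
            boxes.append(
                BoxSpec(
                    box_id=box_id,
                    size_class=size,
                    side_cm=side,
                    height_cm=height,
                    weight_g=weight,
                    weight_rank=rank,
                )
            )
    rng = np.random.default_rng(sequence_seed)
    ids = [b.box_id for b in boxes]
    sequences = tuple(
        tuple(rng.permutation(ids).tolist()) for _ in range(n_sessions)
    )
    return StudyDesign(
        boxes=tuple(boxes),
        n_sessions=n_sessions,
        n_participants=n_participants,
        sequences=sequences,
    )


def box_volume(box: BoxSpec) -> float:
    """Outer volume in cm^3: side x side x height (lid included)."""
    if box.side_cm <= 0 or box.height_cm <= 0:
        raise InvalidInputError("box dimensions must be positive")
    return box.side_cm * box.side_cm * box.height_cm


def box_density(box: BoxSpec, round_2dp: bool = False) -> float:
    """Density in g/cm^3; ``round_2dp`` applies half-up display rounding."""
    d = box.weight_g / box_volume(box)
    if round_2dp:
        # half-up at 2 decimals, matching the printed stimulus table
        return float(np.floor(d * 100 + 0.5) / 100)
    return d


def comparison_pairs(design: StudyDesign) -> list[ComparisonPair]:
    """All same-weight pairs of adjacent size classes, each unordered pair once.

    In the default design there are 8: small-medium at {235, 455, 649, 1140} g
    and medium-large at {455, 649, 1140, 2199} g.
    """
    pairs = []
    for smaller_size, larger_size in zip(SIZE_CLASSES[:-1], SIZE_CLASSES[1:]):
        smaller = [b for b in design.boxes if b.size_class == smaller_size]
        larger = {b.weight_g: b for b in design.boxes if b.size_class == larger_size}
        for b in smaller:
            other = larger.get(b.weight_g)
            if other is not None:
                pairs.append(
                    ComparisonPair(
                        smaller_box_id=b.box_id,
                        larger_box_id=other.box_id,
                        weight_g=b.weight_g,
                    )
                )
    pairs.sort(key=lambda p: (_SIZE_RANK[design.box(p.smaller_box_id).size_class], p.weight_g))
    return pairs


def total_comparisons(design: StudyDesign, per_condition: bool = False) -> int:
    """Comparisons per participant (pairs x sessions); whole cohort if ``per_condition``.

    Default design: 8 x 3 = 24 per participant, 744 over 31 participants.
    """
    per_participant = len(comparison_pairs(design)) * design.n_sessions
    if per_condition:
        return per_participant * design.n_participants
    return per_participant


# --- YAML round trip ------------------------------------------------------

def design_to_yaml(design: StudyDesign, path) -> None:
    payload = {
        "n_sessions": design.n_sessions,
        "n_participants": design.n_participants,
        "sequences": [list(s) for s in design.sequences],
        "boxes": [
            {
                "box_id": b.box_id,
                "size_class": b.size_class,
                "side_cm": b.side_cm,
                "height_cm": b.height_cm,
                "weight_g": b.weight_g,
                "weight_rank": b.weight_rank,
            }
            for b in design.boxes
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def design_from_yaml(path) -> StudyDesign:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    boxes = tuple(BoxSpec(**b) for b in payload["boxes"])
    return StudyDesign(
        boxes=boxes,
        n_sessions=payload["n_sessions"],
        n_participants=payload["n_participants"],
        sequences=tuple(tuple(s) for s in payload.get("sequences", [])),
    )


def with_participants(design: StudyDesign, n: int) -> StudyDesign:
    """Copy of the design with a different cohort size."""
    return replace(design, n_participants=n)


def load_bundled_design() -> StudyDesign:
    """The default design as shipped in the package's YAML data file."""
    from importlib.resources import files

    path = files("ssiweight").joinpath("data/default_design.yaml")
    with path.open(encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    boxes = tuple(BoxSpec(**b) for b in payload["boxes"])
    return StudyDesign(
        boxes=boxes,
        n_sessions=payload["n_sessions"],
        n_participants=payload["n_participants"],
        sequences=tuple(tuple(s) for s in payload.get("sequences", [])),
    )
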