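"""Experimental design: condition matrix, trial schedules, stimulus grids.

The perceptual task is a 2AFC color-dominance judgment: each stimulus is
a 128 x 128 grid of blue/orange blocks with a slight majority of one
color.  After a first independent response, the participant sees three
scripted peer responses and responds again.  The design crosses
congruency (peer majority agrees/disagrees with the first response),
absolute net public information |NPI| in {1, 3}, and correctness of the
peer majority — eight cells in total.

Because peer responses are scripted by *correctness* rather than by
agreement with the (unknown in advance) first response, the schedule
balances the four peer-correctness patterns — all right (RRR), two right
(RRW), one right (RWW), none right (WWW) — in equal quarters, and the
dominant color in equal halves.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import product
from typing import FrozenSet, Tuple

import numpy as np

__all__ = [
    "COLORS",
    "ConditionCell",
    "TrialSpec",
    "Schedule",
    "StimulusGrid",
    "build_design_matrix",
    "generate_schedule",
    "generate_stimulus",
    "PATTERNS",
]

COLORS = ("blue", "orange")

#: canonical peer-correctness patterns, keyed by number of correct peers
PATTERNS = {
    3: ("right", "right", "right"),
    2: ("right", "right", "wrong"),
    1: ("right", "wrong", "wrong"),
    0: ("wrong", "wrong", "wrong"),
}


@dataclass(frozen=True)
class ConditionCell:
    """One cell of the 2 x 2 x 2 design."""

    congruency: str  # "congruent" | "incongruent"
    abs_npi: int  # 1 | 3
    majority_correct: str  # "right" | "wrong"

    def __post_init__(self) -> None:
        if self.congruency not in ("congruent", "incongruent"):
            raise ValueError(f"bad congruency {self.congruency!r}")
        if self.abs_npi not in (1, 3):
            raise ValueError(f"bad abs_npi {self.abs_npi!r}")
        if self.majority_correct not in ("right", "wrong"):
            raise ValueError(f"bad majority_correct {self.majority_correct!r}")


@dataclass(frozen=True)
class TrialSpec:
    """One scripted trial: true dominant color plus peer correctness triple."""

    trial_index: int
    true_color: str
    peer_correctness: Tuple[str, str, str]

    def __post_init__(self) -> None:
        if self.trial_index < 0:
            raise ValueError("trial_index must be >= 0")
        if self.true_color not in COLORS:
            raise ValueError(f"bad true_color {self.true_color!r}")
        if len(self.peer_correctness) != 3 or any(
            p not in ("right", "wrong") for p in self.peer_correctness
        ):
            raise ValueError(f"bad peer_correctness {self.peer_correctness!r}")

    @property
    def n_peers_correct(self) -> int:
        return sum(p == "right" for p in self.peer_correctness)


@dataclass(frozen=True)
class Schedule:
    """An ordered, seeded trial schedule."""

    trials: Tuple[TrialSpec, ...]
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["trial_index", "true_color", "peer1_correct", "peer2_correct", "peer3_correct"]
            )
            for t in self.trials:
                w.writerow([t.trial_index, t.true_color, *t.peer_correctness])

    @classmethod
    def from_csv(cls, path, seed: int = -1) -> "Schedule":
        trials = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                trials.append(
                    TrialSpec(
                        trial_index=int(row["trial_index"]),
                        true_color=row["true_color"],
                        peer_correctness=(
                            row["peer1_correct"],
                            row["peer2_correct"],
                            row["peer3_correct"],
                        ),
                    )
                )
        return cls(trials=tuple(trials), seed=seed)


@dataclass(frozen=True)
class StimulusGrid:
    """A 128 x 128 block grid with an exact dominant-color count."""

    cells: np.ndarray = field(repr=False)  # array of "blue"/"orange"
    dominant_color: str
    dominant_fraction: float

    def __post_init__(self) -> None:
        if self.cells.shape != (128, 128):
            raise ValueError(f"grid must be 128 x 128, got {self.cells.shape}")

    @property
    def dominant_count(self) -> int:
        return int(np.sum(self.cells == self.dominant_color))


def build_design_matrix() -> FrozenSet[ConditionCell]:
    """All crossings of congruency x |NPI| x majority correctness (8 cells)."""
    return frozenset(
        ConditionCell(c, a, r)
        for c, a, r in product(("congruent", "incongruent"), (1, 3), ("right", "wrong"))
    )


def generate_schedule(n_trials: int = 60, seed: int = 0) -> Schedule:
    """Build a seeded schedule with balanced patterns and colors.

    The four peer-correctness patterns each fill a quarter of the trials
    and each dominant color fills half.  When ``n_trials`` is divisible
    by 8, patterns are balanced within each color half; otherwise the
    pattern-color pairing is randomized (counts stay exact).  Within each
    triple, which peer slot is right/wrong is shuffled per trial.
    """
    if n_trials % 4 != 0:
        raise ValueError(
            f"n_trials must be divisible by 4 so the four peer-correctness "
            f"patterns balance exactly (got {n_trials})"
        )
    rng = np.random.default_rng(seed)
    per_pattern = n_trials // 4
    if n_trials % 8 == 0:
        # orthogonal: each pattern appears equally often within each color half
        cells = [
            (color, k)
            for color in COLORS
            for k in PATTERNS
            for _ in range(per_pattern // 2)
        ]
    else:
        colors = [COLORS[0]] * (n_trials // 2) + [COLORS[1]] * (n_trials // 2)
        patterns = [k for k in PATTERNS for _ in range(per_pattern)]
        rng.shuffle(patterns)
        cells = list(zip(colors, patterns))
    order = rng.permutation(len(cells))
    trials = []
    for idx, cell_i in enumerate(order):
        color, k = cells[cell_i]
        triple = tuple(str(p) for p in rng.permutation(PATTERNS[k]))
        trials.append(TrialSpec(trial_index=idx, true_color=color, peer_correctness=triple))
    return Schedule(trials=tuple(trials), seed=seed)


def generate_stimulus(
    true_color: str, dominant_fraction: float = 0.53, seed: int = 0
) -> StimulusGrid:
    """Place exactly ``round(dominant_fraction * 16384)`` dominant blocks.

    Fractions at or below 0.5 (no majority) or at/above 1 are rejected;
    fractions that round to all 16384 cells (>= 0.99997) are rejected
    rather than silently saturated.
    """
    if true_color not in COLORS:
        raise ValueError(f"bad true_color {true_color!r}")
    if not (0.5 < dominant_fraction < 1.0):
        raise ValueError(
            f"dominant_fraction must lie in (0.5, 1), got {dominant_fraction}"
        )
    n_cells = 128 * 128
    n_dom = int(round(dominant_fraction * n_cells))
    if n_dom >= n_cells:
        raise ValueError(
            f"dominant_fraction {dominant_fraction} rounds to a single-color grid"
        )
    other = COLORS[1 - COLORS.index(true_color)]
    flat = np.array([true_color] * n_dom + [other] * (n_cells - n_dom))
    rng = np.random.default_rng(seed)
    rng.shuffle(flat)
    return StimulusGrid(
        cells=flat.reshape(128, 128),
        dominant_color=true_color,
        dominant_fraction=dominant_fraction,
    )
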