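"""Copeland pairwise-tournament scoring of candidate degradation enzymes.

Within one pathway step, every candidate enzyme is compared against every
other candidate, substrate by substrate.  A comparison awards +1 to the
enzyme with the stronger binding (larger absolute energy), −1 to the weaker,
and 0 to both on a tie.  An enzyme's per-substrate score is the sum of its
marks against all opponents; its comprehensive score sums the per-substrate
scores over the step's substrates.  All scores are exact integers.

Comparison is on the magnitude of the energy, which for the all-negative
energies of docking output is the same as "more negative wins"; the
magnitude reading extends the convention unambiguously to mixed-sign user
data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .pathway_model import BindingEnergyTable, Enzyme, PathwayStep

__all__ = [
    "EnzymeScoreCard",
    "pairwise_mark",
    "enzyme_substrate_score",
    "comprehensive_score",
    "step_scores",
    "score_cards_frame",
    "write_score_cards",
]


@dataclass(frozen=True)
class EnzymeScoreCard:
    """Copeland marks for one enzyme within its step.

    For a step with k candidates and m substrates, each per-substrate score
    lies in [−(k−1), k−1] and the comprehensive score in [−m(k−1), m(k−1)].
    """

    enzyme: Enzyme
    per_substrate_score: Mapping[str, int]
    comprehensive_score: int

    @property
    def number(self) -> int:
        return self.enzyme.number


def pairwise_mark(energy_a: float, energy_b: float, tolerance: float = 0.0) -> int:
    """Copeland mark for candidate a against candidate b on one substrate.

    Returns +1 if a binds more strongly (|energy_a| exceeds |energy_b| by
    more than ``tolerance``), −1 if more weakly, 0 if within tolerance.
    Antisymmetric under argument swap.
    """
    if not (math.isfinite(energy_a) and math.isfinite(energy_b)):
        raise ValueError(f"energies must be finite, got {energy_a!r}, {energy_b!r}")
    if tolerance < 0:
        raise ValueError(f"tolerance must be nonnegative, got {tolerance}")
    diff = abs(energy_a) - abs(energy_b)
    if abs(diff) <= tolerance:
        return 0
    return 1 if diff > 0 else -1


def enzyme_substrate_score(
    enzyme: Enzyme,
    substrate: str,
    step: PathwayStep,
    table: BindingEnergyTable,
    tolerance: float = 0.0,
) -> int:
    """Sum of an enzyme's pairwise marks against every other candidate of its
    step, on one substrate."""
    own = table.energy(enzyme.pdb_id, substrate)
    return sum(
        pairwise_mark(own, table.energy(other.pdb_id, substrate), tolerance)
        for other in step.candidates
        if other.number != enzyme.number
    )


def comprehensive_score(
    enzyme: Enzyme,
    step: PathwayStep,
    table: BindingEnergyTable,
    tolerance: float = 0.0,
) -> EnzymeScoreCard:
    """Score card for one enzyme: per-substrate marks and their sum."""
    per_substrate = {
        substrate: enzyme_substrate_score(enzyme, substrate, step, table, tolerance)
        for substrate in step.substrate_names
    }
    return EnzymeScoreCard(
        enzyme=enzyme,
        per_substrate_score=per_substrate,
        comprehensive_score=sum(per_substrate.values()),
    )


def step_scores(
    step: PathwayStep, table: BindingEnergyTable, tolerance: float = 0.0
) -> dict[int, EnzymeScoreCard]:
    """Score cards for every candidate of a step, keyed by enzyme number.

    Because every pairwise comparison awards opposite marks to its two
    participants, the per-substrate scores (and hence the comprehensive
    scores) over a step always sum to zero.
    """
    return {
        enzyme.number: comprehensive_score(enzyme, step, table, tolerance)
        for enzyme in step.candidates
    }


def score_cards_frame(cards: Mapping[int, EnzymeScoreCard]) -> pd.DataFrame:
    """Score cards as a table: one row per enzyme, one column per substrate,
    plus the comprehensive score."""
    rows = []
    for number in sorted(cards):
        card = cards[number]
        row: dict[str, object] = {
            "number": number,
            "pdb_id": card.enzyme.pdb_id,
            "step_id": card.enzyme.step_id,
        }
        row.update(card.per_substrate_score)
        row["comprehensive_score"] = card.comprehensive_score
        rows.append(row)
    return pd.DataFrame(rows)


def write_score_cards(cards: Mapping[int, EnzymeScoreCard], path: str | Path) -> None:
    score_cards_frame(cards).to_csv(path, sep="\t", index=False)
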