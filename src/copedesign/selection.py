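"""Enumeration, scoring, ranking and tie-breaking of inoculation programs.

An inoculation program picks one candidate degradation enzyme per pathway
step (one source bacterium per step).  Programs are identified by the tuple
of global enzyme numbers, e.g. [4, 10, 15, 16].  A program's total score is
the sum of its member enzymes' Copeland comprehensive scores; the complete
program space (the Cartesian product over steps) is enumerated exhaustively,
which is trivial at consortium-design scale.

When several programs share the top score, the winner is the program whose
enzymes — at the steps where the tied programs differ — have the smallest
summed variance of binding energy across their step's substrates: among
equally ranked candidates, the one with the most uniform affinity over the
pollutant spectrum is preferred.  Exact variance ties fall back to the
lexicographically smallest tuple.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .copeland import EnzymeScoreCard, step_scores
from .pathway_model import BindingEnergyTable, Enzyme, PathwaySpec

__all__ = [
    "RunConfig",
    "InoculationProgram",
    "RankingResult",
    "enumerate_programs",
    "score_program",
    "rank_programs",
    "enzyme_variance",
    "tiebreak",
    "select_best",
    "greedy_select",
    "rank_effect_correlation",
    "ranking_frame",
    "write_ranking",
]


@dataclass(frozen=True)
class RunConfig:
    """Knobs of the selection pipeline.

    tolerance
        Energy difference below which two binding energies count as tied in
        a pairwise comparison.  Default 0: equality at input precision.
    variance_denominator
        "n" (population variance, the default) or "n-1" (sample variance)
        for the tie-break spread of an enzyme's energies over its step's
        substrates.
    tie_policy
        Only "smallest-variance-then-lexicographic" is implemented.
    """

    tolerance: float = 0.0
    variance_denominator: str = "n"
    tie_policy: str = "smallest-variance-then-lexicographic"

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be nonnegative")
        if self.variance_denominator not in ("n", "n-1"):
            raise ValueError(
                f"variance_denominator must be 'n' or 'n-1', "
                f"got {self.variance_denominator!r}"
            )
        if self.tie_policy != "smallest-variance-then-lexicographic":
            raise ValueError(f"unknown tie policy {self.tie_policy!r}")

    @property
    def ddof(self) -> int:
        return 0 if self.variance_denominator == "n" else 1

    def provenance(self) -> dict[str, object]:
        return {
            "tolerance": self.tolerance,
            "variance_denominator": self.variance_denominator,
            "tie_policy": self.tie_policy,
        }


@dataclass(frozen=True)
class InoculationProgram:
    """One enzyme number per pathway step, with its aggregate score."""

    enzyme_numbers: tuple[int, ...]
    total_score: int
    tiebreak_variance: float | None = None

    def __str__(self) -> str:
        return "[" + ", ".join(str(n) for n in self.enzyme_numbers) + "]"


@dataclass
class RankingResult:
    """All programs of a study, ranked, with the tie structure made explicit."""

    programs: list[InoculationProgram]
    top_tie_group: list[InoculationProgram]
    selected: InoculationProgram
    provenance: dict[str, object] = field(default_factory=dict)

    @property
    def max_score(self) -> int:
        return self.programs[0].total_score


def enumerate_programs(spec: PathwaySpec) -> list[tuple[int, ...]]:
    """All enzyme-number tuples, one candidate per step, in lexicographic
    order.  The count is the product of the per-step candidate counts."""
    per_step = []
    for step in spec.steps:
        if not step.candidates:
            raise ValueError(f"step {step.step_id!r} has no candidates")
        per_step.append(sorted(e.number for e in step.candidates))
    return list(itertools.product(*per_step))


def score_program(
    program: Sequence[int],
    step_cards: Sequence[Mapping[int, EnzymeScoreCard]],
) -> InoculationProgram:
    """Total score of a program: the sum of its members' comprehensive scores."""
    if len(program) != len(step_cards):
        raise ValueError(
            f"program has {len(program)} members but the study has "
            f"{len(step_cards)} steps"
        )
    total = 0
    for number, cards in zip(program, step_cards):
        if number not in cards:
            raise KeyError(f"enzyme number {number} is not a candidate of its step")
        total += cards[number].comprehensive_score
    return InoculationProgram(enzyme_numbers=tuple(program), total_score=total)


def _all_step_cards(
    spec: PathwaySpec,
    tables: Iterable[BindingEnergyTable],
    tolerance: float,
) -> list[dict[int, EnzymeScoreCard]]:
    by_step = {t.step_id: t for t in tables}
    cards = []
    for step in spec.steps:
        if step.step_id not in by_step:
            raise KeyError(f"no energy table for step {step.step_id!r}")
        cards.append(step_scores(step, by_step[step.step_id], tolerance))
    return cards


def rank_programs(
    spec: PathwaySpec,
    tables: Iterable[BindingEnergyTable],
    config: RunConfig | None = None,
) -> RankingResult:
    """Score every program and sort by total score (descending; equal scores
    in lexicographic tuple order).  No tie resolution: ``selected`` is the
    first member of the top tie group and carries no tie-break variance."""
    config = config or RunConfig()
    cards = _all_step_cards(spec, tables, config.tolerance)
    scored = [score_program(p, cards) for p in enumerate_programs(spec)]
    scored.sort(key=lambda p: (-p.total_score, p.enzyme_numbers))
    top = [p for p in scored if p.total_score == scored[0].total_score]
    return RankingResult(
        programs=scored,
        top_tie_group=top,
        selected=top[0],
        provenance=config.provenance(),
    )


def enzyme_variance(
    enzyme: Enzyme,
    table: BindingEnergyTable,
    denominator: str = "n",
) -> float:
    """Variance of one enzyme's binding energies across its step's substrates.

    ``denominator`` selects population ("n") or sample ("n-1") variance.
    """
    values = np.array(
        [table.energies[key] for key in table.energies if key[0] == enzyme.pdb_id]
    )
    ddof = 0 if denominator == "n" else 1
    if values.size <= ddof:
        raise ValueError(
            f"enzyme {enzyme.pdb_id!r} has {values.size} energies; "
            f"denominator {denominator!r} needs more"
        )
    return float(np.var(values, ddof=ddof))


def _program_tiebreak_variance(
    program: InoculationProgram,
    differing: Sequence[int],
    spec: PathwaySpec,
    by_step: Mapping[str, BindingEnergyTable],
    denominator: str,
) -> float:
    total = 0.0
    for idx in differing:
        step = spec.steps[idx]
        enzyme = step.enzyme_by_number(program.enzyme_numbers[idx])
        total += enzyme_variance(enzyme, by_step[step.step_id], denominator)
    return total


def tiebreak(
    tie_group: Sequence[InoculationProgram],
    spec: PathwaySpec,
    tables: Iterable[BindingEnergyTable],
    config: RunConfig | None = None,
) -> InoculationProgram:
    """Resolve a group of equally scored programs.

    The variance comparison runs only over the steps at which the tied
    programs actually differ (for a single differing step this is a direct
    comparison of the two candidate enzymes' spreads); exactly tied
    variances fall back to the lexicographically smallest tuple.  The
    returned program carries its summed tie-break variance.
    """
    if not tie_group:
        raise ValueError("tie group is empty")
    config = config or RunConfig()
    scores = {p.total_score for p in tie_group}
    if len(scores) > 1:
        raise ValueError(f"tie group mixes total scores {sorted(scores)}")
    if len(tie_group) == 1:
        return tie_group[0]
    annotated = _annotated_tie_group(tie_group, spec, tables, config)
    return min(annotated, key=lambda p: (p.tiebreak_variance, p.enzyme_numbers))


def _annotated_tie_group(
    tie_group: Sequence[InoculationProgram],
    spec: PathwaySpec,
    tables: Iterable[BindingEnergyTable],
    config: RunConfig,
) -> list[InoculationProgram]:
    by_step = {t.step_id: t for t in tables}
    n_steps = len(tie_group[0].enzyme_numbers)
    differing = [
        i
        for i in range(n_steps)
        if len({p.enzyme_numbers[i] for p in tie_group}) > 1
    ]
    return [
        InoculationProgram(
            enzyme_numbers=p.enzyme_numbers,
            total_score=p.total_score,
            tiebreak_variance=_program_tiebreak_variance(
                p, differing, spec, by_step, config.variance_denominator
            ),
        )
        for p in tie_group
    ]


def select_best(
    spec: PathwaySpec,
    tables: Iterable[BindingEnergyTable],
    config: RunConfig | None = None,
) -> RankingResult:
    """Rank every program, then resolve the top tie group.

    End-to-end selection: Copeland scoring per step, exhaustive program
    enumeration, ranking, smallest-variance tie-break.
    """
    config = config or RunConfig()
    tables = list(tables)
    result = rank_programs(spec, tables, config)
    if len(result.top_tie_group) > 1:
        result.top_tie_group = _annotated_tie_group(
            result.top_tie_group, spec, tables, config
        )
        result.selected = min(
            result.top_tie_group,
            key=lambda p: (p.tiebreak_variance, p.enzyme_numbers),
        )
    return result


def greedy_select(
    spec: PathwaySpec,
    tables: Iterable[BindingEnergyTable],
) -> tuple[int, ...]:
    """Per-step strongest-binder selection for a single-pollutant track.

    Each step must carry exactly one substrate; the candidate with the
    largest-magnitude binding energy wins, ties going to the lowest enzyme
    number.
    """
    by_step = {t.step_id: t for t in tables}
    chosen = []
    for step in spec.steps:
        if len(step.substrate_names) != 1:
            raise ValueError(
                f"greedy selection needs one substrate per step; step "
                f"{step.step_id!r} has {len(step.substrate_names)}"
            )
        substrate = step.substrate_names[0]
        table = by_step[step.step_id]
        best = min(
            step.candidates,
            key=lambda e: (-abs(table.energy(e.pdb_id, substrate)), e.number),
        )
        chosen.append(best.number)
    return tuple(chosen)


def rank_effect_correlation(
    result: RankingResult,
    effect_values: Mapping[tuple[int, ...], float],
) -> float:
    """Pearson correlation between Copeland rank order and observed effects.

    A verification utility for user-supplied downstream measurements (e.g.
    docking energies of the top-ranked programs): ranks 1, 2, … are assigned
    in the result's order to the programs present in ``effect_values`` and
    correlated with the supplied values.
    """
    pairs = [
        (rank, effect_values[p.enzyme_numbers])
        for rank, p in enumerate(result.programs, start=1)
        if p.enzyme_numbers in effect_values
    ]
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 programs with effect values, got {len(pairs)}")
    ranks, effects = zip(*pairs)
    if len(set(ranks)) == 1 or len(set(effects)) == 1:
        raise ValueError("zero variance in ranks or effects")
    r, _ = stats.pearsonr(ranks, effects)
    return float(r)


def ranking_frame(result: RankingResult, spec: PathwaySpec) -> pd.DataFrame:
    """Ranking as a table: program tuple, member PDB ids, score, tie flag."""
    top_score = result.max_score
    rows = []
    for rank, program in enumerate(result.programs, start=1):
        rows.append(
            {
                "rank": rank,
                "program": str(program),
                "pdb_ids": "/".join(
                    spec.enzyme_by_number(n).pdb_id for n in program.enzyme_numbers
                ),
                "total_score": program.total_score,
                "in_top_tie": program.total_score == top_score,
                "tiebreak_variance": program.tiebreak_variance,
                "selected": program.enzyme_numbers
                == result.selected.enzyme_numbers,
            }
        )
    return pd.DataFrame(rows)


def write_ranking(
    result: RankingResult,
    spec: PathwaySpec,
    tsv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> None:
    """Write the ranking as TSV and/or a JSON result document with provenance."""
    if tsv_path is not None:
        ranking_frame(result, spec).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        doc = {
            "selected": list(result.selected.enzyme_numbers),
            "selected_pdb_ids": [
                spec.enzyme_by_number(n).pdb_id
                for n in result.selected.enzyme_numbers
            ],
            "max_score": result.max_score,
            "n_programs": len(result.programs),
            "top_tie_group": [
                {
                    "program": list(p.enzyme_numbers),
                    "tiebreak_variance": p.tiebreak_variance,
                }
                for p in result.top_tie_group
            ],
            "provenance": result.provenance,
        }
        Path(json_path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
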