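"""Shared fixtures and the independent tournament oracle.

The oracle recomputes Copeland scores and program totals with plain nested
loops straight from the raw energies, keeping it independent of the
package's scoring path.
"""

from __future__ import annotations

import itertools

import pytest

from copedesign.pathway_model import (
    BindingEnergyTable,
    Enzyme,
    PathwaySpec,
    PathwayStep,
    builtin_fixtures,
)


@pytest.fixture(scope="session")
def alkane_study():
    return builtin_fixtures()


@pytest.fixture(scope="session")
def alkane_spec(alkane_study):
    return alkane_study[0]


@pytest.fixture(scope="session")
def alkane_tables(alkane_study):
    return alkane_study[1]


def make_step(step_id, energies_by_enzyme, first_number=1):
    """Build a (PathwayStep, BindingEnergyTable) pair from a mapping
    pdb_id -> list of energies (one per substrate)."""
    n_substrates = len(next(iter(energies_by_enzyme.values())))
    substrates = tuple(
        (f"p{i + 1}", f"sub{i + 1}") for i in range(n_substrates)
    )
    candidates = tuple(
        Enzyme(number=first_number + i, pdb_id=pdb_id, organism="test", step_id=step_id)
        for i, pdb_id in enumerate(energies_by_enzyme)
    )
    energies = {
        (pdb_id, f"sub{i + 1}"): float(values[i])
        for pdb_id, values in energies_by_enzyme.items()
        for i in range(n_substrates)
    }
    step = PathwayStep(
        step_id=step_id, name=step_id, candidates=candidates, substrates=substrates
    )
    return step, BindingEnergyTable(step_id=step_id, energies=energies)


def make_study(step_energies):
    """Build a PathwaySpec plus tables from a list of pdb_id->energies maps."""
    steps, tables = [], []
    number = 1
    for s, energies_by_enzyme in enumerate(step_energies):
        step, table = make_step(f"step{s + 1}", energies_by_enzyme, number)
        number += len(energies_by_enzyme)
        steps.append(step)
        tables.append(table)
    return PathwaySpec(track="alkane", steps=tuple(steps)), tables


# ---------------------------------------------------------------------------
# Independent brute-force oracle


def oracle_step_scores(step, table):
    """Plain-loop Copeland tournament: number -> comprehensive score."""
    scores = {}
    for enzyme in step.candidates:
        total = 0
        for _, substrate in step.substrates:
            mine = abs(table.energies[(enzyme.pdb_id, substrate)])
            for other in step.candidates:
                if other.number == enzyme.number:
                    continue
                theirs = abs(table.energies[(other.pdb_id, substrate)])
                if mine > theirs:
                    total += 1
                elif mine < theirs:
                    total -= 1
        scores[enzyme.number] = total
    return scores


def oracle_program_scores(spec, tables):
    """All programs with brute-force totals: dict tuple -> score."""
    by_step = {t.step_id: t for t in tables}
    per_step = [oracle_step_scores(s, by_step[s.step_id]) for s in spec.steps]
    numbers = [sorted(d) for d in per_step]
    return {
        combo: sum(d[n] for d, n in zip(per_step, combo))
        for combo in itertools.product(*numbers)
    }
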