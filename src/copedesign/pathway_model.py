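"""Domain model for degradation-pathway studies.

A *study* consists of a pathway specification — an ordered list of
degradation steps, each with candidate degradation enzymes (identified by
PDB structure and source organism) and one pollutant-specific substrate per
pollutant — together with one binding-energy table per step.  Binding
energies follow the docking/MD convention that a larger absolute (more
negative) value means stronger enzyme–substrate binding and hence stronger
degradation ability.

Enzyme numbers are global across a study: the same PDB structure listed
under two different steps is two distinct candidates with two numbers.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "Pollutant",
    "Enzyme",
    "PathwayStep",
    "BindingEnergyTable",
    "PathwaySpec",
    "ValidationReport",
    "TableLoadError",
    "load_energy_table",
    "write_energy_table",
    "load_pathway_spec",
    "write_pathway_spec",
    "builtin_fixtures",
    "validate_spec",
]

HYDROCARBON_CLASSES = frozenset(
    {"n-alkane", "branched-alkane", "cycloalkane", "aromatic"}
)


class TableLoadError(ValueError):
    """A binding-energy table file could not be parsed into a complete matrix."""


@dataclass(frozen=True)
class Pollutant:
    """A petroleum-hydrocarbon pollutant under study."""

    id: str
    name: str
    hydrocarbon_class: str

    def __post_init__(self) -> None:
        if self.hydrocarbon_class not in HYDROCARBON_CLASSES:
            raise ValueError(
                f"unknown hydrocarbon class {self.hydrocarbon_class!r}; "
                f"expected one of {sorted(HYDROCARBON_CLASSES)}"
            )


@dataclass(frozen=True)
class Enzyme:
    """One candidate degradation enzyme within one pathway step.

    ``number`` is the study-global index used to name inoculation programs
    (e.g. program [4, 10, 15, 16]).  ``pdb_id`` is the PDB structure code;
    the same structure may appear in different steps under different
    numbers.
    """

    number: int
    pdb_id: str
    organism: str
    step_id: str

    def __post_init__(self) -> None:
        if self.number < 1:
            raise ValueError(f"enzyme number must be positive, got {self.number}")
        if not self.pdb_id:
            raise ValueError("pdb_id must be nonempty")


@dataclass(frozen=True)
class PathwayStep:
    """An ordered degradation step: candidates plus one substrate per pollutant."""

    step_id: str
    name: str
    candidates: tuple[Enzyme, ...]
    substrates: tuple[tuple[str, str], ...]  # (pollutant id, substrate name)

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError(f"step {self.step_id!r} has no candidate enzymes")
        if not self.substrates:
            raise ValueError(f"step {self.step_id!r} has no substrates")
        numbers = [e.number for e in self.candidates]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError(
                f"candidate numbers of step {self.step_id!r} must be strictly "
                f"increasing, got {numbers}"
            )

    @property
    def substrate_names(self) -> tuple[str, ...]:
        return tuple(name for _, name in self.substrates)

    def enzyme_by_number(self, number: int) -> Enzyme:
        for enz in self.candidates:
            if enz.number == number:
                return enz
        raise KeyError(f"enzyme number {number} is not a candidate of step {self.step_id!r}")


@dataclass(frozen=True)
class BindingEnergyTable:
    """Enzyme × substrate binding energies for one pathway step.

    Energies are stored as given (unitless here; more negative = stronger
    binding).  Keys are (enzyme PDB id, substrate name); within one step PDB
    ids are unique.
    """

    step_id: str
    energies: Mapping[tuple[str, str], float]

    def energy(self, pdb_id: str, substrate: str) -> float:
        try:
            return self.energies[(pdb_id, substrate)]
        except KeyError:
            raise KeyError(
                f"no energy for enzyme {pdb_id!r} on substrate {substrate!r} "
                f"in step {self.step_id!r}"
            ) from None

    @property
    def pdb_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for pdb_id, _ in self.energies:
            seen.setdefault(pdb_id, None)
        return tuple(seen)

    @property
    def substrates(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, substrate in self.energies:
            seen.setdefault(substrate, None)
        return tuple(seen)


@dataclass(frozen=True)
class PathwaySpec:
    """An ordered degradation track (alkane or aromatic)."""

    track: str
    steps: tuple[PathwayStep, ...]
    pollutants: tuple[Pollutant, ...] = ()

    def step(self, step_id: str) -> PathwayStep:
        for s in self.steps:
            if s.step_id == step_id:
                return s
        raise KeyError(f"no step {step_id!r} in {self.track} track")

    def enzyme_by_number(self, number: int) -> Enzyme:
        for s in self.steps:
            for enz in s.candidates:
                if enz.number == number:
                    return enz
        raise KeyError(f"no enzyme number {number} in {self.track} track")

    @property
    def candidate_counts(self) -> tuple[int, ...]:
        return tuple(len(s.candidates) for s in self.steps)


@dataclass
class ValidationReport:
    """Collected consistency failures for a (spec, tables) pair."""

    failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures

    def __str__(self) -> str:
        if self.ok:
            return "validation passed"
        return "validation failed:\n" + "\n".join(f"  - {f}" for f in self.failures)


# ---------------------------------------------------------------------------
# File I/O


def load_energy_table(path: str | Path, step_id: str) -> BindingEnergyTable:
    """Read a TSV binding-energy matrix.

    Layout: one header row with substrate names, first column the enzyme PDB
    id, remaining cells finite reals.  Raises :class:`TableLoadError` naming
    the offending row/column on a missing cell, a non-numeric cell, or a
    duplicated enzyme row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    if df.shape[1] < 2:
        raise TableLoadError(f"{path}: expected at least one substrate column")
    enzyme_col = df.columns[0]
    substrates = list(df.columns[1:])
    dup = df[enzyme_col][df[enzyme_col].duplicated()]
    if not dup.empty:
        raise TableLoadError(f"{path}: duplicate enzyme row {dup.iloc[0]!r}")
    energies: dict[tuple[str, str], float] = {}
    for _, row in df.iterrows():
        pdb_id = row[enzyme_col]
        for substrate in substrates:
            raw = row[substrate]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                raise TableLoadError(
                    f"{path}: missing energy for enzyme {pdb_id!r}, "
                    f"substrate {substrate!r}"
                )
            try:
                value = float(raw)
            except ValueError:
                raise TableLoadError(
                    f"{path}: non-numeric energy {raw!r} for enzyme {pdb_id!r}, "
                    f"substrate {substrate!r}"
                ) from None
            if not math.isfinite(value):
                raise TableLoadError(
                    f"{path}: non-finite energy for enzyme {pdb_id!r}, "
                    f"substrate {substrate!r}"
                )
            energies[(pdb_id, substrate)] = value
    return BindingEnergyTable(step_id=step_id, energies=energies)


def write_energy_table(table: BindingEnergyTable, path: str | Path) -> None:
    """Write a table in the TSV dialect read by :func:`load_energy_table`.

    Energies are printed with three decimals, the precision used throughout
    reports; loading the file back reproduces every cell exactly at that
    precision.
    """
    path = Path(path)
    substrates = table.substrates
    rows = []
    for pdb_id in table.pdb_ids:
        rows.append(
            [pdb_id] + [f"{table.energy(pdb_id, s):.3f}" for s in substrates]
        )
    df = pd.DataFrame(rows, columns=["enzyme", *substrates])
    df.to_csv(path, sep="\t", index=False)


def _step_from_mapping(raw: Mapping) -> PathwayStep:
    step_id = str(raw["step_id"])
    candidates = tuple(
        Enzyme(
            number=int(c["number"]),
            pdb_id=str(c["pdb_id"]),
            organism=str(c.get("organism", "")),
            step_id=step_id,
        )
        for c in raw["candidates"]
    )
    substrates = tuple(
        (str(s["pollutant"]), str(s["substrate"])) for s in raw["substrates"]
    )
    return PathwayStep(
        step_id=step_id,
        name=str(raw.get("name", step_id)),
        candidates=candidates,
        substrates=substrates,
    )


def load_pathway_spec(path: str | Path) -> PathwaySpec:
    """Read a pathway spec from its YAML description."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    pollutants = tuple(
        Pollutant(
            id=str(p["id"]),
            name=str(p["name"]),
            hydrocarbon_class=str(p["hydrocarbon_class"]),
        )
        for p in raw.get("pollutants", [])
    )
    steps = tuple(_step_from_mapping(s) for s in raw["steps"])
    return PathwaySpec(track=str(raw["track"]), steps=steps, pollutants=pollutants)


def write_pathway_spec(spec: PathwaySpec, path: str | Path) -> None:
    """Serialize a pathway spec to the YAML dialect of :func:`load_pathway_spec`."""
    doc = {
        "track": spec.track,
        "pollutants": [
            {"id": p.id, "name": p.name, "hydrocarbon_class": p.hydrocarbon_class}
            for p in spec.pollutants
        ],
        "steps": [
            {
                "step_id": s.step_id,
                "name": s.name,
                "candidates": [
                    {"number": e.number, "pdb_id": e.pdb_id, "organism": e.organism}
                    for e in s.candidates
                ],
                "substrates": [
                    {"pollutant": pid, "substrate": name}
                    for pid, name in s.substrates
                ],
            }
            for s in spec.steps
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


# ---------------------------------------------------------------------------
# Bundled study


_ALKANE_TABLE_FILES = {
    "single_oxygenation": "alkane_step1_single_oxygenation.tsv",
    "hydroxylation": "alkane_step2_hydroxylation.tsv",
    "secondary_single_oxygenation": "alkane_step3_secondary_single_oxygenation.tsv",
    "secondary_hydroxylation": "alkane_step4_secondary_hydroxylation.tsv",
}


def data_dir() -> Path:
    """Directory holding the bundled study files."""
    return Path(importlib.resources.files("copedesign") / "data")


def builtin_fixtures() -> tuple[PathwaySpec, list[BindingEnergyTable]]:
    """The bundled alkane-track study: spec plus its four energy tables.

    Candidates are numbered 1–5 (single oxygenation), 6–10 (hydroxylation),
    11–15 (secondary single oxygenation) and 16–18 (secondary
    hydroxylation), in the listed candidate order of each step.
    """
    base = data_dir()
    spec = load_pathway_spec(base / "alkane_pathway.yaml")
    tables = [
        load_energy_table(base / fname, step_id)
        for step_id, fname in _ALKANE_TABLE_FILES.items()
    ]
    return spec, tables


def aromatic_track_spec() -> PathwaySpec:
    """The bundled aromatic (benzene) track: structure only, no energies."""
    return load_pathway_spec(data_dir() / "aromatic_pathway.yaml")


def validate_spec(
    spec: PathwaySpec, tables: Iterable[BindingEnergyTable]
) -> ValidationReport:
    """Cross-check a pathway spec against its energy tables.

    Flags steps without a table, cells the spec does not cover (and vice
    versa), non-negative energies, and duplicate enzyme numbers.  Returns a
    report; never raises.
    """
    report = ValidationReport()
    by_step = {t.step_id: t for t in tables}
    seen_numbers: dict[int, str] = {}
    for step in spec.steps:
        for enz in step.candidates:
            if enz.number in seen_numbers:
                report.failures.append(
                    f"enzyme number {enz.number} appears in steps "
                    f"{seen_numbers[enz.number]!r} and {step.step_id!r}"
                )
            seen_numbers[enz.number] = step.step_id
        table = by_step.pop(step.step_id, None)
        if table is None:
            report.failures.append(f"step {step.step_id!r} has no energy table")
            continue
        expected = {
            (e.pdb_id, s) for e in step.candidates for s in step.substrate_names
        }
        present = set(table.energies)
        for pdb_id, substrate in sorted(expected - present):
            report.failures.append(
                f"step {step.step_id!r}: missing energy for ({pdb_id}, {substrate})"
            )
        for pdb_id, substrate in sorted(present - expected):
            report.failures.append(
                f"step {step.step_id!r}: table cell ({pdb_id}, {substrate}) "
                f"not covered by the spec"
            )
        for key in sorted(expected & present):
            value = table.energies[key]
            if not math.isfinite(value):
                report.failures.append(
                    f"step {step.step_id!r}: non-finite energy at {key}"
                )
            elif value >= 0:
                report.failures.append(
                    f"step {step.step_id!r}: non-negative energy {value} at {key}"
                )
    for step_id in by_step:
        report.failures.append(f"table for unknown step {step_id!r}")
    return report
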