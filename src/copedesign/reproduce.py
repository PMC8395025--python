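"""One-shot re-derivation of the bundled study's reference results.

The bundled alkane-track study has a known outcome: 375 candidate programs,
a top Copeland score of 22 shared by programs [4, 7, 15, 16] and
[4, 10, 15, 16], hydroxylation-step tie-break variances 2439.414 (No. 7,
1MHZ) and 1817.936 (No. 10, 6VK6), and final selection [4, 10, 15, 16]
(3E5K / 6VK6 / 4CAZ / 1FZI).  This module recomputes every one of those
quantities from the bundled energy tables and diffs them against the
reference, so a single call certifies the whole pipeline end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .pathway_model import builtin_fixtures
from .selection import RunConfig, enzyme_variance, select_best

__all__ = ["ReproductionReport", "reproduce_reference_results"]

REFERENCE = {
    "n_programs": 375,
    "max_score": 22,
    "top_tie_group": [(4, 7, 15, 16), (4, 10, 15, 16)],
    "tiebreak_variances": {7: 2439.414, 10: 1817.936},
    "selected": (4, 10, 15, 16),
    "selected_pdb_ids": ("3E5K", "6VK6", "4CAZ", "1FZI"),
}

VARIANCE_TOL = 1e-3


@dataclass
class ReproductionReport:
    """Computed quantities, and any mismatches against the reference."""

    computed: dict = field(default_factory=dict)
    mismatches: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.mismatches

    def __str__(self) -> str:
        lines = [
            f"programs enumerated : {self.computed['n_programs']}",
            f"maximum score       : {self.computed['max_score']}",
            "top tie group       : "
            + ", ".join(str(list(p)) for p in self.computed["top_tie_group"]),
            "tie-break variances : "
            + ", ".join(
                f"No. {n} -> {v:.3f}"
                for n, v in sorted(self.computed["tiebreak_variances"].items())
            ),
            f"selected program    : {list(self.computed['selected'])} "
            f"({' / '.join(self.computed['selected_pdb_ids'])})",
        ]
        if self.ok:
            lines.append("all reference checks passed")
        else:
            lines.append("MISMATCHES:")
            lines.extend(f"  - {m}" for m in self.mismatches)
        return "\n".join(lines)


def reproduce_reference_results(
    config: RunConfig | None = None,
) -> ReproductionReport:
    """Run the full pipeline on the bundled study and diff against reference.

    With the default configuration (tolerance 0, population variance) every
    check passes; altered configurations run the same pipeline and report
    the resulting deviations instead of failing.
    """
    config = config or RunConfig()
    spec, tables = builtin_fixtures()
    result = select_best(spec, tables, config)
    hydrox = spec.step("hydroxylation")
    table2 = next(t for t in tables if t.step_id == "hydroxylation")
    variances = {
        n: enzyme_variance(
            hydrox.enzyme_by_number(n), table2, config.variance_denominator
        )
        for n in (7, 10)
    }
    report = ReproductionReport(
        computed={
            "n_programs": len(result.programs),
            "max_score": result.max_score,
            "top_tie_group": sorted(
                p.enzyme_numbers for p in result.top_tie_group
            ),
            "tiebreak_variances": variances,
            "selected": result.selected.enzyme_numbers,
            "selected_pdb_ids": tuple(
                spec.enzyme_by_number(n).pdb_id
                for n in result.selected.enzyme_numbers
            ),
            "provenance": result.provenance,
        }
    )
    c, ref = report.computed, REFERENCE
    if c["n_programs"] != ref["n_programs"]:
        report.mismatches.append(
            f"program count: expected {ref['n_programs']}, got {c['n_programs']}"
        )
    if c["max_score"] != ref["max_score"]:
        report.mismatches.append(
            f"maximum score: expected {ref['max_score']}, got {c['max_score']}"
        )
    if c["top_tie_group"] != ref["top_tie_group"]:
        report.mismatches.append(
            f"top tie group: expected {ref['top_tie_group']}, "
            f"got {c['top_tie_group']}"
        )
    for n, expected in ref["tiebreak_variances"].items():
        got = c["tiebreak_variances"][n]
        if abs(got - expected) > VARIANCE_TOL:
            report.mismatches.append(
                f"variance of No. {n}: expected {expected:.3f}, got {got:.3f}"
            )
    if c["selected"] != ref["selected"]:
        report.mismatches.append(
            f"selected program: expected {list(ref['selected'])}, "
            f"got {list(c['selected'])}"
        )
    if c["selected_pdb_ids"] != ref["selected_pdb_ids"]:
        report.mismatches.append(
            f"selected PDB ids: expected {ref['selected_pdb_ids']}, "
            f"got {c['selected_pdb_ids']}"
        )
    return report
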