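"""Resolve the top tie by the smallest-variance rule and name the winner.

The two top programs differ only at the hydroxylation step, so the
tie-break compares the spread of the two candidate enzymes' binding
energies across that step's three substrates (population variance,
denominator n).  Writes the tie-break table and the final selection.

Finding: No. 7 (1MHZ) has variance 2439.414 and No. 10 (6VK6) 1817.936;
the smaller spread selects [4, 10, 15, 16] = 3E5K / 6VK6 / 4CAZ / 1FZI —
cytochrome P450 of Streptomyces avermitilis, methane monooxygenase
hydroxylase of Methylosinus trichosporium OB3b, aldehyde dehydrogenase of
Pseudomonas aeruginosa, and methane monooxygenase hydroxylase of
Methylococcus capsulatus.
"""

import json
from pathlib import Path

import pandas as pd

from copedesign.pathway_model import builtin_fixtures
from copedesign.selection import RunConfig, enzyme_variance, select_best, write_ranking

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    spec, tables = builtin_fixtures()
    config = RunConfig()
    result = select_best(spec, tables, config)

    rows = []
    for program in result.top_tie_group:
        rows.append(
            {
                "program": str(program),
                "total_score": program.total_score,
                "tiebreak_variance": round(program.tiebreak_variance, 3),
                "selected": program.enzyme_numbers == result.selected.enzyme_numbers,
            }
        )
    table = pd.DataFrame(rows)
    print(table.to_string(index=False))

    # the same spread, per tied hydroxylation candidate, with both denominators
    step = spec.step("hydroxylation")
    t2 = next(t for t in tables if t.step_id == "hydroxylation")
    for n in (7, 10):
        enzyme = step.enzyme_by_number(n)
        print(
            f"No. {n} ({enzyme.pdb_id}): variance(n) = "
            f"{enzyme_variance(enzyme, t2, 'n'):.3f}, variance(n-1) = "
            f"{enzyme_variance(enzyme, t2, 'n-1'):.3f}"
        )

    pdb_ids = " / ".join(
        spec.enzyme_by_number(n).pdb_id for n in result.selected.enzyme_numbers
    )
    print(f"\nselected program: {result.selected} ({pdb_ids})")

    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "tiebreak.tsv", sep="\t", index=False)
    write_ranking(result, spec, json_path=RESULTS / "selection.json")
    print(f"wrote {RESULTS / 'tiebreak.tsv'} and {RESULTS / 'selection.json'}")


if __name__ == "__main__":
    main()
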