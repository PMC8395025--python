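"""Enumerate and rank every inoculation program of the bundled study.

One candidate per step over (5, 5, 5, 3) candidate sets gives 375 programs;
each program's score is the sum of its members' comprehensive Copeland
scores.  Writes the full ranking and prints the tie structure at the top.

Finding: the maximum score is 22, shared by exactly two programs,
[4, 7, 15, 16] and [4, 10, 15, 16] — they agree everywhere except the
hydroxylation step (No. 7 = 1MHZ vs No. 10 = 6VK6), which the variance
tie-break resolves in the next script.
"""

from pathlib import Path

from copedesign.pathway_model import builtin_fixtures
from copedesign.selection import rank_programs, ranking_frame

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    spec, tables = builtin_fixtures()
    result = rank_programs(spec, tables)

    print(f"programs enumerated: {len(result.programs)}")
    print(f"maximum score      : {result.max_score}")
    print(f"score range        : {result.programs[-1].total_score} .. "
          f"{result.max_score}")
    print("top tie group      :")
    for program in result.top_tie_group:
        pdb_ids = " / ".join(
            spec.enzyme_by_number(n).pdb_id for n in program.enzyme_numbers
        )
        print(f"  {program} ({pdb_ids}), score {program.total_score}")

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "program_ranking.tsv"
    ranking_frame(result, spec).to_csv(out, sep="\t", index=False)
    print(f"\nwrote full ranking to {out}")


if __name__ == "__main__":
    main()
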