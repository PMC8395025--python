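"""Copeland tournament per pathway step on the bundled alkane-track study.

For each of the four degradation steps, every candidate enzyme is compared
pairwise against its step rivals on the step's three pollutant-specific
substrates, and the per-substrate marks are summed into a comprehensive
score.  Writes one score card per candidate and prints the step winners.

Finding: each step has a clear Copeland winner — 3E5K (+8) for single
oxygenation, 1MHZ and 6VK6 tied (+4) for hydroxylation, 4CAZ (+8) for
secondary single oxygenation and 1FZI (+2) for secondary hydroxylation —
so two programs will share the top combined score downstream.
"""

from pathlib import Path

import pandas as pd

from copedesign.copeland import score_cards_frame, step_scores
from copedesign.pathway_model import builtin_fixtures, validate_spec

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    spec, tables = builtin_fixtures()
    report = validate_spec(spec, tables)
    assert report.ok, str(report)

    by_step = {t.step_id: t for t in tables}
    frames = []
    for step in spec.steps:
        cards = step_scores(step, by_step[step.step_id])
        frames.append(score_cards_frame(cards))
        best = max(cards.values(), key=lambda c: c.comprehensive_score)
        winners = [
            c.enzyme.pdb_id
            for c in cards.values()
            if c.comprehensive_score == best.comprehensive_score
        ]
        print(
            f"{step.name:30s} winner(s): {', '.join(winners)} "
            f"(score {best.comprehensive_score:+d})"
        )

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "score_cards.tsv"
    merged = pd.concat(frames, ignore_index=True)
    cols = ["number", "pdb_id", "step_id", "comprehensive_score"]
    substrate_cols = [c for c in merged.columns if c not in cols]
    merged[cols + substrate_cols].to_csv(out, sep="\t", index=False)
    print(f"\nwrote {len(merged)} score cards to {out}")


if __name__ == "__main__":
    main()
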