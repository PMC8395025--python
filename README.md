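# copedesign

Design of microbial inoculation programs for petroleum-hydrocarbon
bioremediation from enzyme–substrate binding energies.

## The problem

Bioremediation of an oil-contaminated site needs a *consortium*: one
degradation bacterium — in practice, one degradation enzyme — for each step
of the pollutant-degradation pathway. For alkane pollutants
(*n*-tetradecane, norphytane, cyclopentane) four steps are retained: single
oxygenation, hydroxylation, secondary single oxygenation and secondary
hydroxylation. Each step has several candidate enzymes (identified by PDB
structure and source organism), and each candidate's degradation ability
toward each pollutant is proxied by a docking/MD binding energy *E*, with
the convention that a larger |*E*| (more negative value) means stronger
binding and hence stronger degradation ability.

Picking the per-pollutant best enzyme per step is not possible in general —
the best binder for one pollutant is rarely the best for the others — so
the selection is made by the **Copeland method**, a pairwise-majority
ranking rule from social choice theory:

- Within one step, for each substrate, every pair of candidate enzymes is
  compared: the stronger binder is marked +1, the weaker −1, equal
  strength 0.
- An enzyme's **comprehensive score** is the sum of its marks over all
  opponents and all of the step's substrates. For a step with *k*
  candidates and *m* substrates it lies in [−*m*(*k*−1), +*m*(*k*−1)], and
  the scores within a step always sum to zero.
- An **inoculation program** picks one enzyme per step, written as the
  tuple of global enzyme numbers (e.g. `[4, 10, 15, 16]`); its total score
  sums the members' comprehensive scores. All programs (the Cartesian
  product over steps) are enumerated exhaustively.
- Programs tied at the top score are separated by the **smallest-variance
  rule**: at the steps where the tied programs differ, the program whose
  enzyme has the smallest variance of binding energy across the step's
  substrates — the most uniform affinity over the pollutant spectrum —
  wins. The variance is the population variance S² = Σ(X−X̄)²/n by default
  (the sample denominator n−1 is available by configuration).

For the single-pollutant aromatic (benzene) track no tournament is needed:
the strongest binder is selected greedily per step.

The package bundles a complete alkane-track study (four binding-energy
tables over 18 candidate enzymes) as its reference dataset, ships a
synthetic-study generator with a planted dominant enzyme per step for
validating the pipeline's recovery behaviour, and exposes both a Python API
and a `copedesign` command line.

## Worked example

```python
from copedesign import builtin_fixtures, select_best

spec, tables = builtin_fixtures()
result = select_best(spec, tables)
print(len(result.programs), result.max_score)
for p in result.top_tie_group:
    print(p, p.total_score, round(p.tiebreak_variance, 3))
print(result.selected)
```

prints

```
375 22
[4, 7, 15, 16] 22 2439.414
[4, 10, 15, 16] 22 1817.936
[4, 10, 15, 16]
```

i.e. the (5, 5, 5, 3) candidate sets yield 375 programs; two programs share
the top Copeland score of 22, differing only in the hydroxylation step
(No. 7 = 1MHZ vs No. 10 = 6VK6); the variance tie-break (1817.936 <
2439.414) selects `[4, 10, 15, 16]` — 3E5K / 6VK6 / 4CAZ / 1FZI, i.e. the
cytochrome P450 of *Streptomyces avermitilis*, the methane monooxygenase
hydroxylase of *Methylosinus trichosporium* OB3b, the aldehyde
dehydrogenase of *Pseudomonas aeruginosa* and the methane monooxygenase
hydroxylase of *Methylococcus capsulatus*.

The same run from the shell, with a full diff against the bundled study's
reference results:

```
copedesign reproduce
```

## Analysis scripts

The `analysis/` directory re-derives the bundled study step by step, each
script writing its table under `results/`:

1. `01_score_enzymes.py` — Copeland score cards per step (`score_cards.tsv`)
2. `02_rank_programs.py` — all 375 programs ranked (`program_ranking.tsv`)
3. `03_select_best.py` — variance tie-break and final selection
   (`tiebreak.tsv`, `selection.json`)
4. `04_recovery_simulation.py` — planted-winner recovery of the pipeline on
   synthetic studies across a separation grid (`recovery.tsv`)

## Layout

- `src/copedesign/pathway_model.py` — domain types, TSV/YAML readers and
  writers, bundled study, validation
- `src/copedesign/copeland.py` — the pairwise tournament
- `src/copedesign/selection.py` — enumeration, ranking, tie-break, greedy
  selection, rank-vs-effect correlation
- `src/copedesign/synthetic.py` — synthetic studies with planted winners
- `src/copedesign/reproduce.py` — one-shot reference-result reproduction
- `src/copedesign/cli.py` — `copedesign rank | greedy | simulate | recover |
  reproduce`
- `docs/methods.md` — model, assumptions, parameter choices, limitations
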