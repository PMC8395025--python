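# Methods

## Model and procedure

The pipeline selects a microbial consortium — one degradation enzyme per
pathway step — from per-step enzyme × substrate binding-energy matrices.
It treats the binding energies as fixed inputs (they come from docking and
molecular-dynamics calculations that are outside this package's scope) and
makes only ordinal use of them within each substrate column, plus one
cardinal use in the tie-break variance.

1. **Pairwise marks.** Within a step, for each substrate, candidates a and
   b are compared on binding strength |E|: the stronger gets +1, the weaker
   −1, both 0 on a tie. Strength is the magnitude of the energy; for the
   all-negative energies of docking output this is identical to "more
   negative wins", and it extends the convention unambiguously to
   mixed-sign user data. The comparison admits a tolerance (default 0, i.e.
   equality at input precision): the bundled tables contain near-ties
   decided at the third decimal (−28.647 vs −28.650), and any nonzero
   default tolerance would change the reference outcome, so the tolerance
   is a configuration knob only.
2. **Scores.** Per-substrate scores sum the marks over all opponents;
   the comprehensive score sums over the step's substrates. Scores are
   exact integers throughout — no floating aggregation — which makes the
   zero-sum identity (scores within a step sum to 0) and the bounds
   (±m(k−1)) exact invariants, both property-tested.
3. **Programs.** All cross-step combinations are enumerated (Cartesian
   product, lexicographic in enzyme number). Exhaustive enumeration is the
   method: at consortium-design scale (hundreds of programs) no shortcut is
   warranted. A program's total score sums its members' comprehensive
   scores; ranking is by total score, descending, equal scores in
   lexicographic tuple order for determinism.
4. **Tie-break.** Among top-score programs, each program gets the summed
   variance of its member enzymes' binding energies across their step's
   substrates, restricted to the steps where the tied programs differ; the
   smallest summed variance wins. For a single differing step this is a
   direct comparison of two enzymes' spreads; the generalisation to a sum
   over all differing positions reduces to that case and keeps the rule
   total. Exactly tied variances fall back to the lexicographically
   smallest tuple.
5. **Greedy track.** For a single-pollutant track (the benzene pathway)
   each step simply takes the strongest binder, ties to the lowest enzyme
   number. The bundled aromatic pathway ships as structural metadata with
   its published winners; its numeric energy table is not available, so
   greedy selection is exercised on synthetic single-substrate studies.

## Variance denominator

The tie-break variance uses the population denominator n by default. The
reference tie-break values for the bundled study (2439.414 for No. 7 /
1MHZ, 1817.936 for No. 10 / 6VK6) are reproduced exactly by Σ(X−X̄)²/n over
the three hydroxylation-step substrates; the sample denominator n−1 gives
3659.120 and 2726.905 instead. Both are available (`variance_denominator`
= "n" | "n-1"); the `reproduce` command run with "n-1" demonstrates the
mismatch explicitly. Since n = 3 for every step of the bundled study, and
both denominators are positive monotone transforms of the same sum of
squares over equal n, the choice never changes which of two same-step
enzymes wins a tie — only the printed values.

## Tunable parameters

| knob | default | meaning |
|---|---|---|
| `tolerance` | 0 | energy gap (same units as the tables) treated as a pairwise tie |
| `variance_denominator` | `n` | population vs sample tie-break variance |
| `tie_policy` | smallest-variance-then-lexicographic | only implemented policy |

Energies are stored unitless: the inputs' units are whatever the upstream
docking/MD produced, and every operation is either ordinal or
unit-covariant (variances scale as c² under rescaling by c, preserving the
tie-break argmin — tested).

## Synthetic studies

`generate_study` draws each cell as baseline_mean + N(0, noise_sd²) and
shifts one planted enzyme per step by −planted_shift on every substrate.
Defaults mirror the bundled study: 4 steps, (5, 5, 5, 3) candidates, 3
substrates per step, baseline −80, noise SD 8 (the scale and spread of the
bundled tables), planted shift 40 = 5 noise SDs — a clearly dominant
candidate, as the strongest binders in the bundled tables are. Strict
negativity is guaranteed by requiring baseline_mean ≤ −10·noise_sd and
redrawing the (practically impossible) non-negative draws, so "more
negative = stronger" is never ambiguous. A single study seed drives
`numpy.random.default_rng`; replicate i of a recovery experiment runs on
seed + i, making every experiment bit-reproducible.

What the generator emulates: per-step candidate structure, negative
energies at realistic magnitude, and a dominant enzyme with controllable
separation. What it does not: correlations between substrates of the same
enzyme (real tables show strong enzyme effects across substrates),
heavy-tailed docking error, or near-tie structure at the third decimal.
Passing recovery tests therefore show that the pipeline identifies a
planted dominant combination under independent Gaussian noise — not that
docking energies themselves are this well behaved.

Measured behaviour (analysis/04, 200 replicates per point, noise SD 8):
recovery is at chance at zero separation and reaches ≥ 0.99 by 3–5 noise
SDs. Under the null (no planted signal) the hit rate matches the symmetry
prediction Π 1/k_s within binomial confidence bounds.

## Numerical choices and degenerate inputs

- Marks and scores are integers; the only floating-point quantities are
  energies, variances and the Pearson utility.
- A single-candidate step scores 0 (no opponents) and contributes nothing
  to program differentiation; enumeration still includes it.
- Variance with denominator n−1 requires ≥ 2 substrate energies; with n it
  is defined (0) for a single value.
- `rank_effect_correlation` (Pearson r between Copeland rank order and
  user-supplied downstream effect values, e.g. docking energies of the
  top-ranked programs) requires ≥ 3 programs and nonzero variance in both
  series; it is a verification utility only and plays no part in
  selection.
- Malformed table files (missing, non-numeric, duplicated rows) fail the
  load with the offending row/column named; cross-validation of a spec
  against its tables (`validate_spec`) collects failures into a report
  instead of raising.

## Problem sizes

The bundled study is tiny (18 enzymes, 54 energy cells, 375 programs) and
runs in milliseconds. Recovery experiments in the tests and analysis
scripts use 120–500 replicates per condition, enough for the binomial
intervals reported alongside each rate; the full suite runs in well under
a minute.

## Known limitations

- The Copeland tournament uses only ordinal information within a substrate
  column; two enzymes separated by 0.003 or by 50 energy units earn the
  same mark. The tolerance knob can coarsen this, at the cost of changing
  the reference outcome.
- Equal weighting of pollutants/substrates is hard-coded; no alternative
  voting rules (Borda etc.) are implemented.
- The tie-break variance is not scale-invariant (it is unit-covariant);
  comparing variances across steps with different energy scales would be
  meaningless, which is why the rule only ever compares within the
  differing steps of a tie.
- The aromatic track carries no numeric fixture; its published selection
  is metadata, not a computation of this package.
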