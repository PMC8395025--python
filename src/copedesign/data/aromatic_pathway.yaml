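# Aromatic (benzene) degradation track.  Shipped as structural metadata only:
# the published study selected these steps greedily (strongest binder per
# step) and did not print the underlying benzene-track binding energies, so
# no numeric tables accompany this spec.  The `selected` block records the
# published greedy winners.
track: aromatic
pollutants:
  - id: bz
    name: benzene
    hydrocarbon_class: aromatic
steps:
  - step_id: hydroxylation
    name: hydroxylation
    candidates:
      - {number: 1, pdb_id: 1FZI, organism: Methylococcus capsulatus}
      - {number: 2, pdb_id: 1MHZ, organism: Methylosinus trichosporium}
      - {number: 3, pdb_id: 3B9N, organism: Geobacillus thermodenitrificans}
      - {number: 4, pdb_id: 6D7K, organism: Methylosinus sporium}
      - {number: 5, pdb_id: 6VK6, organism: Methylosinus trichosporium OB3b}
    substrates:
      - {pollutant: bz, substrate: benzene}
  - step_id: dioxygenation
    name: dioxygenation (ring cleavage)
    candidates:
      - {number: 6, pdb_id: 2IGA, organism: Brevibacterium fuscum}
      - {number: 7, pdb_id: 1DLT, organism: Acinetobacter baylyi ADP1}
      - {number: 8, pdb_id: 2AZQ, organism: Pseudomonas putida}
      - {number: 9, pdb_id: 3HPY, organism: Pseudomonas alkylphenolica}
      - {number: 10, pdb_id: 2XSR, organism: Acinetobacter radioresistens}
    substrates:
      - {pollutant: bz, substrate: catechol}
  - step_id: hydrolysis
    name: hydrolysis
    candidates:
      - {number: 11, pdb_id: 3G02, organism: Aspergillus niger}
      - {number: 12, pdb_id: 4XBT, organism: Rhodococcus erythropolis}
      - {number: 13, pdb_id: 4IO0, organism: Bacillus megaterium}
    substrates:
      - {pollutant: bz, substrate: (Z)-hexa-3-enedioic acid}
  - step_id: coa
    name: CoA pathway
    candidates:
      - {number: 14, pdb_id: 4Z3W, organism: Geobacter metallireducens GS-15}
    substrates:
      - {pollutant: bz, substrate: 3-oxoadipate}
selected:
  - {step_id: hydroxylation, pdb_id: 6VK6}
  - {step_id: dioxygenation, pdb_id: 1DLT}
  - {step_id: hydrolysis, pdb_id: 4XBT}
  - {step_id: coa, pdb_id: 4Z3W}
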