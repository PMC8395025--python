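# Alkane-track degradation pathway: candidate enzymes (PDB structures and
# source organisms) for each of the four retained degradation steps, and the
# pollutant-specific substrate each step acts on.  Enzyme numbers are global
# across the study; an enzyme appearing in two steps is two candidates.
track: alkane
pollutants:
  - id: c14
    name: n-tetradecane
    hydrocarbon_class: n-alkane
  - id: nph
    name: norphytane
    hydrocarbon_class: branched-alkane
  - id: cp
    name: cyclopentane
    hydrocarbon_class: cycloalkane
steps:
  - step_id: single_oxygenation
    name: single oxygenation
    candidates:
      - {number: 1, pdb_id: 6CXH, organism: Methylomicrobium alcaliphilum 20Z}
      - {number: 2, pdb_id: 4USQ, organism: Cellvibrio sp. BR}
      - {number: 3, pdb_id: 6HNS, organism: Nitrincola lacisaponensis}
      - {number: 4, pdb_id: 3E5K, organism: Streptomyces avermitilis}
      - {number: 5, pdb_id: 1SMJ, organism: Bacillus megaterium}
    substrates:
      - {pollutant: c14, substrate: n-tetradecane}
      - {pollutant: nph, substrate: norphytane}
      - {pollutant: cp, substrate: cyclopentane}
  - step_id: hydroxylation
    name: hydroxylation
    candidates:
      - {number: 6, pdb_id: 1FZI, organism: Methylococcus capsulatus}
      - {number: 7, pdb_id: 1MHZ, organism: Methylosinus trichosporium}
      - {number: 8, pdb_id: 3B9N, organism: Geobacillus thermodenitrificans}
      - {number: 9, pdb_id: 6D7K, organism: Methylosinus sporium}
      - {number: 10, pdb_id: 6VK6, organism: Methylosinus trichosporium OB3b}
    substrates:
      - {pollutant: c14, substrate: tridecane-1-ol}
      - {pollutant: nph, substrate: "2,6,10,14-tetramethylpentadecan-1-ol"}
      - {pollutant: cp, substrate: cyclopentanol}
  - step_id: secondary_single_oxygenation
    name: secondary single oxygenation
    candidates:
      - {number: 11, pdb_id: 3E5K, organism: Streptomyces avermitilis}
      - {number: 12, pdb_id: 7BU3, organism: Escherichia coli}
      - {number: 13, pdb_id: 1Q1N, organism: Saccharomyces cerevisiae}
      - {number: 14, pdb_id: 6K10, organism: Staphylococcus aureus}
      - {number: 15, pdb_id: 4CAZ, organism: Pseudomonas aeruginosa}
    substrates:
      - {pollutant: c14, substrate: dodecan-1-ol}
      - {pollutant: nph, substrate: "2,6,10-trimethylpentadecane-1,14-diol"}
      - {pollutant: cp, substrate: cyclopentanone}
  - step_id: secondary_hydroxylation
    name: secondary hydroxylation
    candidates:
      - {number: 16, pdb_id: 1FZI, organism: Methylococcus capsulatus}
      - {number: 17, pdb_id: 6D7K, organism: Methylosinus sporium}
      - {number: 18, pdb_id: 6VK6, organism: Methylosinus trichosporium OB3b}
    substrates:
      - {pollutant: c14, substrate: hexan-1-ol}
      - {pollutant: nph, substrate: 2-methyl-1-propanol}
      - {pollutant: cp, substrate: dihydrofuran-2(3H)-one}
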