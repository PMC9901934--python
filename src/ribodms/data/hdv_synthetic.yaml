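# Synthetic reconstruction of a hdv self-cleaving ribozyme
# reference definition. Sequence and exact pairings are constructed, not
# the deposited construct; length, region names, region sizes and
# catalytic positions follow the study design this package analyses.
name: hdv_synthetic
display_offset: 1
leader: GGCUCUUCAGGU
sequence: GGCUCGGAGCAGCAGCAUCAAGGCACAUCACCGAGCCAAUGCCGGACGUCAGCCAGCGAAGCUGGCUGAUGUCCCAUGCAAUGCUGC
structure: "(((((((.{{.[[[[[[....[[[......)))))))...]]]((((((((((((((...))))))))))))))...}}..]]]]]]"
regions:
  H1: P1
  H2: T1
  H3: P2
  H4: P3
  H5: P4
catalytic: [74]
notes: >-
  HDV genomic-ribozyme architecture: P1 (7 bp), P2 (6 bp), P3 (3 bp),
  the long P4 hairpin (14 bp) and the 2-bp pseudoknot T1; catalytic
  cytosine C75 (position 74) unpaired between P4 and T1.
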