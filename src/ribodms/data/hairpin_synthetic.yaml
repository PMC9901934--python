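# Synthetic reconstruction of a hairpin self-cleaving ribozyme
# reference definition. Sequence and exact pairings are constructed, not
# the deposited construct; length, region names, region sizes and
# catalytic positions follow the study design this package analyses.
name: hairpin_synthetic
display_offset: 1
leader: GGUAUAUUACGG
sequence: GCCAGUAAGUCAGCAGGUUCGACCCUGCGAUACGGCAGUCUUCGAAGGCUGCCACAUCAGACUAAACUGGC
structure: "((((((......(((((......))))).....(((((((......)))))))............))))))"
regions:
  H1: P1
  H2: P2
  H3: P3
catalytic: [28, 58]
notes: >-
  Hairpin-ribozyme architecture: two helical arms with stems P1, P2
  and P3 flanking the internal loops A (positions 6-11, 28-32) and
  B (53-64); catalytic G29 (position 28) and A59 (position 58) sit in
  the loops, mirroring the loop-A/loop-B active site.
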