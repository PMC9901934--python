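# Synthetic reconstruction of a twister self-cleaving ribozyme
# reference definition. Sequence and exact pairings are constructed, not
# the deposited construct; length, region names, region sizes and
# catalytic positions follow the study design this package analyses.
name: twister_synthetic
display_offset: 1
leader: GGAUCCAAGU
sequence: AGCGGCUAGGACCAGUUUCACUGAGCUGCAGCAAAUACGUGCAAGUCC
structure: ".(((((..[[[[((((...)))).))))).(((......)))..]]]]"
regions:
  H1: P2
  H2: T1
  H3: P4
  H4: T2
catalytic: [0, 38]
notes: >-
  Twister-family architecture: stems P2 and P4, pseudoknots T1 (4 bp)
  and T2 (3 bp); general acid A1 (position 0) and general base G39
  (position 38) unpaired. 1-based display labels match these names.
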