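# Synthetic reconstruction of a hammerhead self-cleaving ribozyme
# reference definition. Sequence and exact pairings are constructed, not
# the deposited construct; length, region names, region sizes and
# catalytic positions follow the study design this package analyses.
name: hammerhead_synthetic
display_offset: 1
leader: GGAUGUAAC
sequence: GCUGUCAGUGAUCGACAGCCUGAAGGCAGCUUCGCUGCGAAUCAA
structure: "((((((.......))))))......(((((...)))))......."
regions:
  H1: P1
  H2: P2
catalytic: [24, 38]
notes: >-
  Type-III hammerhead architecture: stems P1 and P2 with terminal
  loops carrying the loop-loop tertiary contact; the CUGA U-turn
  (positions 19-22) and catalytic G25 (24) / G39 (38) are unpaired.
  The -1C of the motif is the final base of the 5' leader.
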