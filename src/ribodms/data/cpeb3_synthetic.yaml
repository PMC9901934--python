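# Synthetic reconstruction of a cpeb3 self-cleaving ribozyme
# reference definition. Sequence and exact pairings are constructed, not
# the deposited construct; length, region names, region sizes and
# catalytic positions follow the study design this package analyses.
name: cpeb3_synthetic
display_offset: 1
leader: GGGUUCAACUGG
sequence: GGGCAGCAGAGCCUCAAGAUCAGGCAGCUGUCCUCAGGCAGGCAGUUCGACUGCCACAGCCUGAUCAAC
structure: "(((((((.[.(((.........))).))))))).(((((.(((((.....)))))...)))))..]..."
regions:
  H1: P1
  H2: T1
  H3: P3
  H4: P2
  H5: P4
catalytic: [56]
notes: >-
  HDV-family (CPEB3) architecture: nested double pseudoknot with
  P1 (7 bp), P2 (5 bp), P3 (3 bp), P4 (5 bp) and the single-pair
  pseudoknot T1; catalytic cytosine C57 (position 56) unpaired.
  The adjacent non-canonical U:U of T1 is deliberately unannotated.
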