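# Methods

## Pipeline model

A sequencing read from a co-transcriptional self-cleavage experiment is
modelled as `pad + [leader] + ribozyme`, where `pad` is one of four
template-switching-oligo (TSO) prefixes of lengths 3–6 that stagger the
sequencing frame, and the 5' `leader` (the upstream cleavage product) is
present only on *uncleaved* molecules. Variant calling slides a window of
the reference length L over the read and keeps the offset with the fewest
mismatches (ties broken toward the smallest offset, a deterministic
convention); the mismatches at that offset are the genotype. Reads whose
best window still has more than `max_muts` (default 2) mismatches are
tallied but not analysed — the model is substitution-only, because doped
solid-phase synthesis produces substitutions, not indels. Cleavage
classification requires an exact match of the leader's 3'-terminal
k = min(len(leader), offset) bases immediately 5' of the window
(configurably ≤1 mismatch); k = 0 means no evidence and the read counts as
cleaved. Only the given strand is searched — library orientation is fixed by
the RT/PCR design.

Per genotype and replicate, FC = N_clv/(N_clv+N_unclv) and RA = FC/FC_wt.
By default RA is averaged across the replicates where the genotype has at
least `min_reads` (default 10) reads; a pooled-count mode sums counts across
replicates before a single FC/RA. Desk-scale simulated runs (10⁵ reads per
replicate) leave each double mutant with only ~7 reads pooled, so the
analysis scripts and the end-to-end checks use pooled counts with
`min_reads = 1`; at the read depths of a real experiment (millions of reads)
the default replicate-averaged mode is the faithful choice. RA is not capped
at 1.

Epistasis is ε = log(RA_ij/(RA_i·RA_j)), natural log by default. A floor
(default 10⁻³) keeps ε finite when an RA estimate is exactly zero; the floor
value matters at low depth (a zero-cleaved-read double is reported at
ε = log(floor/(RA_i·RA_j))) and is logged in outputs. The false-positive
filter builds the pooled distribution of differences RA_ij − RA_k over all
doubles and both constituent singles, takes its standard deviation σ, and
flags a record when either |RA_ij − RA_i| or |RA_ij − RA_j| < c·σ (c default
1; combiner configurable to "both"). Flagged ε values are set aside as
unreliable, not altered. Positive epistasis is ε > 0, negative ε < 0, and
|ε| > 1 is additionally reported as "strong".

Two distinct structural predicates are implemented side by side, because the
analyses use both: mismatch categorisation of in-region doubles counts a GU
wobble as "no mismatch" (categories WC/GU, 1-mismatch, 2-mismatch), while
the on/off-diagonal split calls a partner-position double "on-diagonal" only
when it restores a strict Watson-Crick pair (wobble-restoring doubles go
off-diagonal). Doubles spanning two different paired regions belong to
neither region's panel. Mann-Whitney U comparisons use full enumeration of
all C(m+n, m) label assignments for small samples (|x|·|y| ≤ 10⁴, ties by
the midrank ½ convention; identical multisets give p = 1 exactly) and the
tie-corrected normal approximation with continuity correction otherwise —
the exact mode is custom because enumeration with ties has no off-the-shelf
implementation; the approximate branch is scipy's.

Duplex free energies of paired regions excise loop nucleotides: the pos5 and
pos3 bases of a region's pairs form two strands that pair in register, and
ΔG°37 = intermolecular initiation (+4.10 kcal/mol) + nearest-neighbor stack
terms + 0.50 per terminal AU/GU pair (+0.43 for a self-complementary
duplex). Stacking parameters are the Turner-2004/Xia-1998 set, embedded as
`data/nn_stacks_turner2004.tsv` with citation; the two tandem-GU motifs that
set special-cases carry the Mathews-1999 value (−0.5). Neglecting terminal
loops is deliberate — it treats internal and terminal stems uniformly; the
bimolecular initiation term is a constant across regions and therefore
cannot affect the stability correlation, which is the Pearson r of median
single-mutant RA (over a region's paired positions) against ΔG, requiring
≥3 regions and flagged NaN for degenerate (constant) inputs.

## Synthetic data and what it does (not) show

The generator draws each read's genotype by independent per-position
multinomials (wild-type 0.97, each alternative 0.01), assigns it a cleavage
probability from a planted activity model, and emits
`pad + [leader] + mutated sequence` with a Bernoulli(FC) cleavage state,
optional uniform per-base errors (default 0 — the experimental protocol is
not error-modelled), and a truth table of planted FC/RA plus the sampled
per-replicate tallies. Identical configurations are byte-identical. TSO pads
are seeded random sequences whose ends are constrained not to mimic the
leader's terminal bases, as real TSOs are designed not to resemble the
cleavage-product end — otherwise a quarter of cleaved reads would
systematically misclassify.

The planted model is multiplicative on RA and pair-aware: each mutation at
an unpaired position costs `loop_single_effect` (default 0.85); each
catalytic-position mutation costs `catalytic_effect` (default 0, no rescue
possible regardless of partner); each base pair actually *disrupted* after
applying the genotype costs `stem_single_effect` (default 0.2) — a stem
mutation that leaves a WC or GU pair costs nothing, so a compensatory double
recovers full activity; a second disrupted pair multiplies an extra
`pair_synergy` (default 0.5), planting negative epistasis for double
disruptions; `compensatory_bonus` (default 1) can push pair-restoring
doubles above wild type; optional log-normal jitter (`noise_sd`) and
per-region stem-effect overrides (`region_effects`, used to plant
stability-dependent mutational effects) complete the model. Genotypes of
order ≥ 3 are sampled and emitted but receive the product of their singles'
effects and are excluded from activity/epistasis analysis.

This generator reproduces the statistical structure the pipeline must
detect — leader-based cleavage states, frame offsets, doping-driven genotype
frequencies, compensatory/catalytic signatures — but not PCR bias, duplicate
reads, unequal replicate pooling, quality-score structure, indels, or real
thermodynamic folding; passing recovery tests therefore validates the
estimator chain, not any biological claim about a particular ribozyme. The
five shipped reference definitions are likewise synthetic reconstructions:
family-correct lengths, region counts and catalytic positions with invented
sequences, sufficient for everything computed here (which depends only on
those properties), but not substitutes for the deposited constructs.

## Numerical and design choices

- Coordinates are 0-based and cleavage-site-anchored; each reference file
  carries a `display_offset` so reports print 1-based figure-style labels
  (the hammerhead's "-1C" is the leader's final base, documented in its
  fixture rather than renumbered).
- Enumeration order is position-major with alternatives in fixed A<C<G<U
  order (reference base skipped); heatmap axes use the same order. The
  3L×3L heatmap stores single-mutant RA on the diagonal, symmetric doubles
  off it, and NaN (never 0) for impossible or unobserved cells.
- Counting batches reads by length so the window scan is a few vectorised
  comparisons per offset; the batch path is tested for exact agreement with
  the single-read caller.
- Study-scale problem sizes used throughout the checks: the twister-like
  end-to-end run is 3 replicates × 10⁵ reads (singles ~700 reads pooled,
  doubles ~7), and the CPEB3-like wild-type-FC recovery run is one replicate
  of 10⁵ reads. At ~7 reads per double, double-mutant RA estimates are
  quantised (multiples of ~1/7) and a double with zero cleaved reads hits
  the ε floor; coverage of all 10 152 doubles is a Poisson race with mean
  ~6 never-observed genotypes. These depth effects — not estimator defects —
  bound what the desk-scale run can show; they disappear at the read depths
  of a real experiment.

## Known limitations

- No kinetic rate fitting (single 30-min time point by design), no
  shrinkage/error model on FC, no 3-way epistasis, no indel handling, no
  reverse-complement search, no cross-region double-mutant panels (a
  cross-region mode exists for exploration only).
- The Mann-Whitney exact mode enumerates up to ~2·10⁵ assignments and
  silently switches to the approximation beyond that.
- Terminal-loop thermodynamics and tertiary contacts are outside the duplex
  ΔG model; the stability correlation inherits that approximation.
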