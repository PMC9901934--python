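"""Doped-library read simulation with a planted, structure-aware activity model.

The generator emulates a co-transcriptional self-cleavage experiment on a
doped mutant library: each template position carries the reference base with
probability 0.97 and each alternative base with probability 0.01; molecules
self-cleave with a genotype-dependent probability (fraction cleaved, FC);
sequencing reads of cleaved molecules lack the 5' leader while uncleaved
reads retain it; every read is prefixed by one of four phased
template-switching-oligo (TSO) pads of lengths 3-6 that stagger the
sequencing frame.

The planted activity model is pair-aware: a mutation in a paired region is
only penalised if it actually disrupts a base pair (Watson-Crick or GU
wobble), so a compensatory double that restores a pair recovers full
activity — the qualitative structure the analysis is meant to detect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import (
    BASES,
    Genotype,
    RibozymeReference,
    WT,
    enumerate_double_mutants,
    enumerate_single_mutants,
)

WC_PAIRS = {"AU", "UA", "GC", "CG"}
WOBBLE_PAIRS = {"GU", "UG"}
CANONICAL_PAIRS = WC_PAIRS | WOBBLE_PAIRS


@dataclass
class ActivityModel:
    """Multiplicative relative-activity model used to plant ground truth.

    wt_fc
        Fraction cleaved of the unmutated reference (e.g. 0.90 for a
        CPEB3-like run, 0.60 for a twister-like run).
    stem_single_effect
        RA multiplier per base pair that a genotype disrupts (a paired-region
        mutation that leaves the pair WC/GU, e.g. creates a wobble, is free).
    loop_single_effect
        RA multiplier per mutation at an unpaired, non-catalytic position.
    catalytic_effect
        RA multiplier per mutation at a catalytic position; applied
        regardless of any partner mutation (catalytic residues admit no
        compensatory rescue).
    compensatory_bonus
        Extra RA multiplier (>= 1) for an order-2 genotype whose two
        substitutions sit on the two sides of one base pair, each disrupting
        it alone, while together restoring a WC/GU pair.
    pair_synergy
        Extra RA multiplier per disrupted pair beyond the first (synergy of
        multiple breaks in the same structure): two broken pairs are worse
        than additive, planting the negative epistasis observed off the
        anti-diagonal of paired regions.
    noise_sd
        Standard deviation of optional log-scale jitter applied to RA.
    region_effects
        Optional per-region override of ``stem_single_effect`` (region name
        -> multiplier), used to plant stability-dependent mutational effects.
    """

    wt_fc: float = 0.90
    stem_single_effect: float = 0.2
    loop_single_effect: float = 0.85
    catalytic_effect: float = 0.0
    compensatory_bonus: float = 1.0
    pair_synergy: float = 0.5
    noise_sd: float = 0.0
    region_effects: dict | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.wt_fc <= 1.0:
            raise ValueError("wt_fc must be in [0,1]")
        for name in ("stem_single_effect", "loop_single_effect", "catalytic_effect"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.compensatory_bonus < 1.0:
            raise ValueError("compensatory_bonus must be >= 1")
        if not 0.0 < self.pair_synergy <= 1.0:
            raise ValueError("pair_synergy must be in (0,1]")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated sequencing run."""

    n_reads: int = 100_000
    n_replicates: int = 3
    seed: int = 0
    doping_rate: float = 0.97
    alt_rate: float = 0.01
    error_rate: float = 0.0
    tso_lengths: tuple[int, ...] = (3, 4, 5, 6)

    def __post_init__(self) -> None:
        if abs(self.doping_rate + 3 * self.alt_rate - 1.0) > 1e-9:
            raise ValueError("doping_rate + 3*alt_rate must equal 1")
        if self.n_reads < 1 or self.n_replicates < 1:
            raise ValueError("n_reads and n_replicates must be positive")


def true_relative_activity(
    ref: RibozymeReference, g: Genotype, model: ActivityModel
) -> float:
    """Planted RA of a genotype under the pair-aware multiplicative model."""
    if g.order == 0:
        return 1.0
    pair_of: dict[int, tuple[int, int]] = {}
    region_of: dict[tuple[int, int], str] = {}
    for region in ref.paired_regions:
        for pair in region.pairs:
            pair_of[pair[0]] = pair
            pair_of[pair[1]] = pair
            region_of[pair] = region.name

    mutated = dict(g.substitutions)
    ra = 1.0
    catalytic_hit = False
    for pos, _alt in g.substitutions:
        if pos in ref.catalytic_positions:
            ra *= model.catalytic_effect
            catalytic_hit = True
        elif pos not in pair_of:
            ra *= model.loop_single_effect

    touched_pairs = {pair_of[p] for p in mutated if p in pair_of and p not in ref.catalytic_positions}
    broken = 0
    for p5, p3 in sorted(touched_pairs):
        b5 = mutated.get(p5, ref.sequence[p5])
        b3 = mutated.get(p3, ref.sequence[p3])
        if b5 + b3 not in CANONICAL_PAIRS:
            effect = model.stem_single_effect
            if model.region_effects:
                effect = model.region_effects.get(region_of[(p5, p3)], effect)
            ra *= effect
            broken += 1
    if broken > 1:
        ra *= model.pair_synergy ** (broken - 1)

    if g.order == 2 and not catalytic_hit:
        (p1, a1), (p2, a2) = g.substitutions
        pair = pair_of.get(p1)
        if pair is not None and pair_of.get(p2) == pair:
            b5, b3 = a1, a2  # p1 < p2 implies p1 is the 5' side of the pair
            ref5, ref3 = ref.sequence[pair[0]], ref.sequence[pair[1]]
            # each single alone disrupts, the double restores
            if (
                b5 + b3 in CANONICAL_PAIRS
                and (b5 + ref3) not in CANONICAL_PAIRS
                and (ref5 + b3) not in CANONICAL_PAIRS
            ):
                ra *= model.compensatory_bonus
    return ra


def assign_ground_truth(
    ref: RibozymeReference,
    model: ActivityModel,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Planted FC/RA for the wild type and every single and double mutant.

    Returns a DataFrame with columns genotype, order, true_ra, true_fc.
    The wild type receives ``wt_fc`` exactly; FC values are clamped to [0,1].
    """
    genotypes = [WT] + enumerate_single_mutants(ref) + enumerate_double_mutants(ref)
    rows = []
    for g in genotypes:
        ra = true_relative_activity(ref, g, model)
        if model.noise_sd > 0 and g.order > 0:
            if rng is None:
                raise ValueError("noise_sd > 0 requires an rng")
            ra *= float(np.exp(rng.normal(0.0, model.noise_sd)))
        fc = model.wt_fc if g.order == 0 else min(1.0, max(0.0, model.wt_fc * ra))
        rows.append((str(g), g.order, ra, fc))
    return pd.DataFrame(rows, columns=["genotype", "order", "true_ra", "true_fc"])


def sample_genotype(
    ref: RibozymeReference, config: SimulationConfig, rng: np.random.Generator
) -> Genotype:
    """One independent per-position multinomial draw from the doped library."""
    subs = []
    for pos in range(ref.length):
        u = rng.random()
        if u >= config.doping_rate:
            alt_idx = min(int((u - config.doping_rate) / config.alt_rate), 2)
            subs.append((pos, ref.alternatives(pos)[alt_idx]))
    return Genotype(tuple(subs))


def make_tso_pads(
    leader: str, lengths: tuple[int, ...], rng: np.random.Generator
) -> list[str]:
    """Seeded TSO pad sequences; rejected if a pad ends like the leader.

    Real TSOs are designed not to mimic the cleavage-product end; without
    this constraint a pad that happens to end with the leader's terminal
    bases would systematically misclassify cleaved reads as uncleaved.
    """
    pads = []
    for n in lengths:
        while True:
            pad = "".join(rng.choice(list(BASES), size=n))
            if not leader or pad[-min(n, len(leader)):] != leader[-min(n, len(leader)):]:
                pads.append(pad)
                break
    return pads


def _fc_lookup(ref, truth, model):
    """FC per genotype string; orders >= 3 get the product of single effects."""
    table = dict(zip(truth["genotype"], truth["true_fc"]))
    single_ra = {
        g: ra
        for g, order, ra in zip(truth["genotype"], truth["order"], truth["true_ra"])
        if order == 1
    }

    def lookup(g: Genotype) -> float:
        key = str(g)
        if key in table:
            return table[key]
        ra = 1.0
        for pos, alt in g.substitutions:
            ra *= single_ra[f"{pos}:{alt}"]
        fc = min(1.0, max(0.0, model.wt_fc * ra))
        table[key] = fc
        return fc

    return lookup


def emit_reads(
    ref: RibozymeReference,
    truth: pd.DataFrame,
    config: SimulationConfig,
    out_dir: str | Path,
    model: ActivityModel | None = None,
) -> dict:
    """Write one FASTQ per replicate plus a truth/count TSV and a config echo.

    Each read is ``pad + (leader if uncleaved) + mutated ribozyme``; the pad
    cycles through the four TSO lengths by read index; cleavage is a
    Bernoulli draw with the genotype's planted FC. Identical configs produce
    byte-identical output. Returns a manifest dict with file paths.
    """
    model = model or ActivityModel()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    L = ref.length
    seq_arr = np.frombuffer(ref.sequence.encode(), dtype="S1")
    base_bytes = np.frombuffer(b"ACGU", dtype="S1")
    # per-position alternative bases in fixed A<C<G<U order, shape (L, 3)
    alts = np.array(
        [[b.encode() for b in ref.alternatives(p)] for p in range(L)], dtype="S1"
    )
    fc_of = _fc_lookup(ref, truth, model)

    ss = np.random.SeedSequence(config.seed)
    pad_rng = np.random.default_rng(ss.spawn(1)[0])
    pads = make_tso_pads(ref.leader, tuple(config.tso_lengths), pad_rng)
    rep_seeds = ss.spawn(config.n_replicates)

    fastq_paths = []
    sampled: dict[str, list[list[int]]] = {}
    n_rep = config.n_replicates
    for r in range(n_rep):
        rng = np.random.default_rng(rep_seeds[r])
        n = config.n_reads
        mut_mask = rng.random((n, L)) < 3 * config.alt_rate
        alt_choice = rng.integers(0, 3, size=(n, L))
        fq = out_dir / f"reads_rep{r + 1}.fastq"
        fastq_paths.append(fq)
        with open(fq, "w") as fh:
            for i in range(n):
                mpos = np.nonzero(mut_mask[i])[0]
                if mpos.size:
                    subs = tuple(
                        (int(p), alts[p, alt_choice[i, p]].decode()) for p in mpos
                    )
                    g = Genotype(subs)
                    arr = seq_arr.copy()
                    arr[mpos] = alts[mpos, alt_choice[i, mpos]]
                    body = arr.tobytes().decode()
                else:
                    g = WT
                    body = ref.sequence
                fc = fc_of(g)
                cleaved = rng.random() < fc
                key = str(g)
                rec = sampled.setdefault(key, [[0, 0] for _ in range(n_rep)])
                rec[r][0 if cleaved else 1] += 1
                read = pads[i % 4] + ("" if cleaved else ref.leader) + body
                if config.error_rate > 0:
                    rarr = np.frombuffer(read.encode(), dtype="S1").copy()
                    errs = np.nonzero(rng.random(rarr.size) < config.error_rate)[0]
                    if errs.size:
                        rarr[errs] = base_bytes[rng.integers(0, 4, size=errs.size)]
                    read = rarr.tobytes().decode()
                fh.write(f"@{ref.name}:rep{r + 1}:{i}\n{read}\n+\n{'I' * len(read)}\n")

    truth_out = truth.copy()
    for r in range(n_rep):
        truth_out[f"rep{r + 1}_cleaved"] = [
            sampled.get(g, [[0, 0]] * n_rep)[r][0] for g in truth_out["genotype"]
        ]
        truth_out[f"rep{r + 1}_uncleaved"] = [
            sampled.get(g, [[0, 0]] * n_rep)[r][1] for g in truth_out["genotype"]
        ]
    truth_path = out_dir / "truth.tsv"
    truth_out.to_csv(truth_path, sep="\t", index=False)

    config_path = out_dir / "sim_config.json"
    echo = {
        "reference": ref.name,
        "model": asdict(model),
        "config": {**asdict(config), "tso_lengths": list(config.tso_lengths)},
        "tso_pads": pads,
    }
    config_path.write_text(json.dumps(echo, indent=2) + "\n")
    return {
        "fastq": [str(p) for p in fastq_paths],
        "truth": str(truth_path),
        "config": str(config_path),
        "pads": pads,
    }
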