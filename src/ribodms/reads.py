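"""Variant calling and cleavage classification of merged sequencing reads.

A sequence-length sliding window is slid over each read; the offset with the
fewest mismatches to the reference defines the genotype (ties broken toward
the smallest offset). A read is uncleaved iff the 5' leader sequence appears
immediately upstream of the matched window (exact suffix match by default).
Substitutions only — the doped-synthesis screen produces no indels.
"""

from __future__ import annotations

import gzip
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .reference import Genotype, RibozymeReference

UNASSIGNED_SHORT = "short"
UNASSIGNED_TOO_MANY = "too_many_mutations"


class FastqError(ValueError):
    """Malformed sequencing input, reported with the failing record index."""


@dataclass
class MappingReport:
    """Read accounting for one counting pass; totals are conserved."""

    total: int = 0
    mapped: int = 0
    mapped_by_order: Counter = field(default_factory=Counter)
    unassigned: Counter = field(default_factory=Counter)
    #: mismatch-count tally of reads rejected for exceeding max_muts, so both
    #: interpretations of "total mapped reads" (<=2 mutations vs any best
    #: match) can be reported.
    excess_mismatch_tally: Counter = field(default_factory=Counter)

    @property
    def conserved(self) -> bool:
        return self.mapped + sum(self.unassigned.values()) == self.total

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "mapped": self.mapped,
            "mapped_by_order": dict(self.mapped_by_order),
            "unassigned": dict(self.unassigned),
            "excess_mismatch_tally": dict(self.excess_mismatch_tally),
            "mapped_any_order": self.total - self.unassigned.get(UNASSIGNED_SHORT, 0),
        }


def call_variant(
    read: str, ref: RibozymeReference, max_muts: int = 2
) -> tuple[Genotype, int] | tuple[None, str]:
    """Best-window genotype for one read, or (None, reason) if unassignable.

    Returns (genotype, offset); the window at ``offset`` has the minimum
    mismatch count over all offsets, and the smallest such offset wins ties.
    """
    L = ref.length
    if len(read) < L:
        return None, UNASSIGNED_SHORT
    read_arr = np.frombuffer(read.encode(), dtype="S1")
    ref_arr = np.frombuffer(ref.sequence.encode(), dtype="S1")
    best_offset = 0
    best_count = L + 1
    for offset in range(len(read) - L + 1):
        count = int(np.count_nonzero(read_arr[offset : offset + L] != ref_arr))
        if count < best_count:
            best_count, best_offset = count, offset
    if best_count > max_muts:
        return None, UNASSIGNED_TOO_MANY
    window = read[best_offset : best_offset + L]
    subs = tuple(
        (i, b) for i, (a, b) in enumerate(zip(ref.sequence, window)) if a != b
    )
    return Genotype(subs), best_offset


def classify_cleavage(
    read: str,
    offset: int,
    ref: RibozymeReference,
    max_leader_mismatches: int = 0,
) -> str:
    """'uncleaved' iff the leader's 3'-terminal bases precede the window.

    Compares the k = min(len(leader), offset) bases immediately 5' of the
    matched window with the leader's 3'-terminal k bases; with k = 0 there
    is no leader evidence and the read is classified cleaved.
    """
    k = min(len(ref.leader), offset)
    if k == 0:
        return "cleaved"
    upstream = read[offset - k : offset]
    suffix = ref.leader[-k:]
    mismatches = sum(a != b for a, b in zip(upstream, suffix))
    return "uncleaved" if mismatches <= max_leader_mismatches else "cleaved"


def _parse_reads(path: str | Path) -> Iterator[str]:
    """Yield read sequences from FASTQ/FASTA (optionally gzipped)."""
    from Bio import SeqIO

    path = Path(path)
    name = path.name.lower()
    opener = gzip.open if name.endswith(".gz") else open
    stem = name[:-3] if name.endswith(".gz") else name
    fmt = "fasta" if stem.endswith((".fa", ".fasta")) else "fastq"
    with opener(path, "rt") as fh:
        it = SeqIO.parse(fh, fmt)
        i = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as e:
                raise FastqError(f"malformed {fmt} record at index {i}: {e}") from e
            yield str(rec.seq).upper().replace("T", "U")
            i += 1


def count_reads(
    reads: str | Path | Iterable[str],
    ref: RibozymeReference,
    max_muts: int = 2,
    replicate: str = "rep1",
    max_leader_mismatches: int = 0,
) -> tuple[pd.DataFrame, MappingReport]:
    """One-pass cleaved/uncleaved counting per genotype.

    ``reads`` may be a FASTQ/FASTA path or an iterable of sequences.
    Returns a counts DataFrame (genotype, replicate, n_cleaved, n_uncleaved)
    and a MappingReport; mapped + unassigned always equals total.

    Reads of identical length are batched so the window scan is a handful of
    vectorised comparisons per offset rather than a per-read Python loop.
    """
    if isinstance(reads, (str, Path)):
        reads = _parse_reads(reads)

    report = MappingReport()
    counts: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    L = ref.length
    ref_arr = np.frombuffer(ref.sequence.encode(), dtype="S1")

    by_length: dict[int, list[str]] = defaultdict(list)
    for read in reads:
        report.total += 1
        if len(read) < L:
            report.unassigned[UNASSIGNED_SHORT] += 1
            continue
        by_length[len(read)].append(read)

    for rlen, batch in by_length.items():
        mat = (
            np.frombuffer("".join(batch).encode(), dtype="S1")
            .reshape(len(batch), rlen)
        )
        n_offsets = rlen - L + 1
        mism = np.empty((len(batch), n_offsets), dtype=np.int32)
        for o in range(n_offsets):
            mism[:, o] = np.count_nonzero(mat[:, o : o + L] != ref_arr, axis=1)
        best_offset = mism.argmin(axis=1)  # argmin takes the smallest offset on ties
        best_count = mism[np.arange(len(batch)), best_offset]
        for i, read in enumerate(batch):
            bc = int(best_count[i])
            if bc > max_muts:
                report.unassigned[UNASSIGNED_TOO_MANY] += 1
                report.excess_mismatch_tally[bc] += 1
                continue
            offset = int(best_offset[i])
            window = read[offset : offset + L]
            g = Genotype(
                tuple(
                    (j, b)
                    for j, (a, b) in enumerate(zip(ref.sequence, window))
                    if a != b
                )
            )
            state = classify_cleavage(read, offset, ref, max_leader_mismatches)
            counts[str(g)][0 if state == "cleaved" else 1] += 1
            report.mapped += 1
            report.mapped_by_order[g.order] += 1

    df = pd.DataFrame(
        [
            (g, replicate, c[0], c[1])
            for g, c in sorted(counts.items(), key=lambda kv: (len(kv[0]), kv[0]))
        ],
        columns=["genotype", "replicate", "n_cleaved", "n_uncleaved"],
    )
    return df, report


def count_replicates(
    fastq_paths: Iterable[str | Path],
    ref: RibozymeReference,
    max_muts: int = 2,
    max_leader_mismatches: int = 0,
) -> tuple[pd.DataFrame, dict[str, MappingReport]]:
    """Count several replicate FASTQs; replicates are labeled rep1, rep2, ..."""
    frames = []
    reports: dict[str, MappingReport] = {}
    for r, path in enumerate(fastq_paths, start=1):
        label = f"rep{r}"
        df, rep = count_reads(
            path, ref, max_muts=max_muts, replicate=label,
            max_leader_mismatches=max_leader_mismatches,
        )
        frames.append(df)
        reports[label] = rep
    return pd.concat(frames, ignore_index=True), reports
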