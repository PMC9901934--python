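"""Ribozyme reference definitions, structure annotation, and mutant-space enumeration.

Coordinate convention: 0-based, cleavage-site anchored — position 0 is the
first nucleotide 3' of the self-cleavage site. Each reference definition
carries a ``display_offset`` so that reports can print the 1-based labels
used in figures (e.g. "C57" means internal position 56 with offset 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

BASES = "ACGU"

#: bracket layers recognised in dot-bracket annotations; extra layers encode
#: pseudoknots (pairs crossing the primary layer).
BRACKET_LAYERS = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")]


class StructureParseError(ValueError):
    """Raised for unbalanced or malformed dot-bracket annotations."""


class GenotypeError(ValueError):
    """Raised for substitutions that are invalid relative to a reference."""


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T->U; reject anything outside {A,C,G,U}."""
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - set(BASES)
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class PairedRegion:
    """A helix: an ordered (outermost-to-innermost) list of (pos5, pos3) pairs."""

    name: str
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for p5, p3 in self.pairs:
            if p5 >= p3:
                raise ValueError(f"region {self.name}: pair ({p5},{p3}) not pos5<pos3")
            if p5 in seen or p3 in seen:
                raise ValueError(f"region {self.name}: duplicated position in pairs")
            seen.update((p5, p3))

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(p for pair in self.pairs for p in pair)

    @property
    def partner(self) -> dict[int, int]:
        d: dict[int, int] = {}
        for p5, p3 in self.pairs:
            d[p5] = p3
            d[p3] = p5
        return d

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class Genotype:
    """A canonically sorted set of (position, alternative base) substitutions.

    Order 0 is the wild type; the main analysis covers orders 0-2, but higher
    orders are representable for read accounting.
    """

    substitutions: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        subs = tuple(sorted((int(p), str(b)) for p, b in self.substitutions))
        object.__setattr__(self, "substitutions", subs)
        positions = [p for p, _ in subs]
        if len(set(positions)) != len(positions):
            raise GenotypeError(f"duplicate positions in genotype {subs}")
        for _, b in subs:
            if b not in BASES:
                raise GenotypeError(f"invalid base {b!r} in genotype")

    @property
    def order(self) -> int:
        return len(self.substitutions)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.substitutions)

    def __str__(self) -> str:
        if not self.substitutions:
            return "WT"
        return ",".join(f"{p}:{b}" for p, b in self.substitutions)

    @classmethod
    def from_string(cls, s: str) -> "Genotype":
        s = s.strip()
        if s in ("", "WT", "wt"):
            return cls()
        subs = []
        for tok in s.split(","):
            p, b = tok.split(":")
            subs.append((int(p), b))
        return cls(tuple(subs))


WT = Genotype()


@dataclass
class RibozymeReference:
    """A ribozyme reference: sequence, leader, structure, catalytic positions.

    ``leader`` is the 5' cleavage product — retained only on uncleaved
    molecules; its presence/absence upstream of the matched ribozyme window
    is the cleavage readout. ``cleavage_site`` anchors the coordinate frame
    (always 0 in the internal convention).
    """

    name: str
    sequence: str
    leader: str
    paired_regions: list[PairedRegion] = field(default_factory=list)
    catalytic_positions: frozenset[int] = frozenset()
    cleavage_site: int = 0
    display_offset: int = 1
    notes: str = ""

    def __post_init__(self) -> None:
        self.sequence = normalize_rna(self.sequence)
        self.leader = normalize_rna(self.leader)
        self.catalytic_positions = frozenset(int(p) for p in self.catalytic_positions)
        L = len(self.sequence)
        seen: set[int] = set()
        for region in self.paired_regions:
            for p5, p3 in region.pairs:
                if not (0 <= p5 < L and 0 <= p3 < L):
                    raise ValueError(
                        f"{self.name}: region {region.name} pair ({p5},{p3}) outside [0,{L})"
                    )
                if p5 in seen or p3 in seen:
                    raise ValueError(
                        f"{self.name}: position reused across regions at pair ({p5},{p3})"
                    )
                seen.update((p5, p3))
        if not self.catalytic_positions <= set(range(L)):
            raise ValueError(f"{self.name}: catalytic positions outside [0,{L})")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def paired_positions(self) -> frozenset[int]:
        return frozenset(p for r in self.paired_regions for p in r.positions)

    def region(self, name: str) -> PairedRegion:
        for r in self.paired_regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def display_label(self, pos: int) -> str:
        """Figure-style label for an internal position (e.g. 56 -> 'C57')."""
        return f"{self.sequence[pos]}{pos + self.display_offset}"

    def alternatives(self, pos: int) -> tuple[str, ...]:
        """The three non-reference bases at ``pos`` in fixed A<C<G<U order."""
        ref_base = self.sequence[pos]
        return tuple(b for b in BASES if b != ref_base)


def parse_structure(
    annotation: str,
    region_labels: Mapping[str, str] | None = None,
) -> list[PairedRegion]:
    """Parse a (possibly pseudoknotted) dot-bracket string into helices.

    Each maximal stack of nested adjacent pairs within one bracket layer
    becomes one region. Regions are named ``H1, H2, ...`` in order of their
    5'-most position; ``region_labels`` maps those default names to final
    names (e.g. ``{"H1": "P1", "H3": "T1"}``).
    """
    pairs_by_layer: list[list[tuple[int, int]]] = []
    for open_ch, close_ch in BRACKET_LAYERS:
        stack: list[int] = []
        layer_pairs: list[tuple[int, int]] = []
        for i, ch in enumerate(annotation):
            if ch == open_ch:
                stack.append(i)
            elif ch == close_ch:
                if not stack:
                    raise StructureParseError(
                        f"unbalanced {close_ch!r} at position {i}"
                    )
                layer_pairs.append((stack.pop(), i))
        if stack:
            raise StructureParseError(
                f"unbalanced {open_ch!r} at position {stack[-1]}"
            )
        pairs_by_layer.append(sorted(layer_pairs))

    known = "." + "".join(o + c for o, c in BRACKET_LAYERS)
    bad = [ch for ch in set(annotation) if ch not in known]
    if bad:
        raise StructureParseError(f"unknown annotation characters: {sorted(bad)}")

    helices: list[tuple[tuple[int, int], ...]] = []
    for layer_pairs in pairs_by_layer:
        current: list[tuple[int, int]] = []
        for p5, p3 in layer_pairs:
            if current and (p5, p3) == (current[-1][0] + 1, current[-1][1] - 1):
                current.append((p5, p3))
            else:
                if current:
                    helices.append(tuple(current))
                current = [(p5, p3)]
        if current:
            helices.append(tuple(current))

    helices.sort(key=lambda h: h[0][0])
    labels = dict(region_labels or {})
    regions = []
    for i, pairs in enumerate(helices, start=1):
        default = f"H{i}"
        regions.append(PairedRegion(labels.get(default, default), pairs))
    return regions


def enumerate_single_mutants(ref: RibozymeReference) -> list[Genotype]:
    """All 3L order-1 genotypes, position-major, alternatives in A<C<G<U order."""
    return [
        Genotype(((pos, alt),))
        for pos in range(ref.length)
        for alt in ref.alternatives(pos)
    ]


def enumerate_double_mutants(ref: RibozymeReference) -> list[Genotype]:
    """All 9·L·(L-1)/2 order-2 genotypes."""
    out = []
    for p1, p2 in itertools.combinations(range(ref.length), 2):
        for a1 in ref.alternatives(p1):
            for a2 in ref.alternatives(p2):
                out.append(Genotype(((p1, a1), (p2, a2))))
    return out


def apply_genotype(ref: RibozymeReference, g: Genotype) -> str:
    """Return the reference sequence with the genotype's substitutions applied."""
    seq = list(ref.sequence)
    for pos, alt in g.substitutions:
        if not (0 <= pos < ref.length):
            raise GenotypeError(f"substitution position {pos} outside [0,{ref.length})")
        if seq[pos] == alt:
            raise GenotypeError(
                f"substitution {pos}:{alt} equals the reference base"
            )
        seq[pos] = alt
    return "".join(seq)


def diff_genotype(ref: RibozymeReference, seq: str) -> Genotype:
    """Recover the genotype as the diff of ``seq`` against the reference."""
    if len(seq) != ref.length:
        raise GenotypeError("sequence length differs from reference")
    subs = tuple(
        (i, b) for i, (a, b) in enumerate(zip(ref.sequence, seq)) if a != b
    )
    return Genotype(subs)


# ---------------------------------------------------------------------------
# reference definition files

def load_reference(path: str | Path) -> RibozymeReference:
    """Load a reference definition from a YAML document.

    Required keys: name, sequence, leader, structure (dot-bracket, multi-layer).
    Optional: regions (map of default helix names H1.. to labels), catalytic
    (0-based positions), display_offset, notes. FASTA is accepted for
    sequence-only import via :func:`load_reference_fasta`.
    """
    doc = yaml.safe_load(Path(path).read_text())
    sequence = normalize_rna(doc["sequence"])
    structure = doc.get("structure", "")
    regions: list[PairedRegion] = []
    if structure:
        if len(structure) != len(sequence):
            raise StructureParseError(
                f"{doc.get('name', path)}: structure length {len(structure)} != "
                f"sequence length {len(sequence)}"
            )
        regions = parse_structure(structure, doc.get("regions"))
    return RibozymeReference(
        name=doc["name"],
        sequence=sequence,
        leader=doc["leader"],
        paired_regions=regions,
        catalytic_positions=frozenset(doc.get("catalytic", [])),
        display_offset=int(doc.get("display_offset", 1)),
        notes=doc.get("notes", ""),
    )


def load_reference_fasta(path: str | Path, leader: str = "") -> RibozymeReference:
    """Sequence-only import from FASTA (first record); no structure annotation."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return RibozymeReference(
        name=rec.id, sequence=str(rec.seq), leader=leader
    )


def builtin_reference_path(name: str) -> Path:
    """Path of a shipped reference definition (e.g. 'twister')."""
    p = Path(__file__).parent / "data" / f"{name}_synthetic.yaml"
    if not p.exists():
        raise FileNotFoundError(p)
    return p


def load_builtin(name: str) -> RibozymeReference:
    return load_reference(builtin_reference_path(name))


BUILTIN_NAMES = ("cpeb3", "hdv", "twister", "hairpin", "hammerhead")
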