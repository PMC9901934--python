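"""Mapping activity and epistasis onto secondary structure.

Two distinct predicates from the analysis are implemented side by side:

* mismatch categorisation of in-region doubles (WC/GU counts a wobble as
  "no mismatch") — the violin-plot split;
* the on/off-diagonal split, where on-diagonal means the double restores a
  strict Watson-Crick pair at partner positions (wobble-restoring doubles
  go off-diagonal).

Also here: exact/approximate Mann-Whitney U comparisons, nearest-neighbor
duplex free energies for paired regions (loop nucleotides excised), and the
median-single-mutant-RA vs delta-G Pearson correlation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .reference import Genotype, PairedRegion, RibozymeReference

WC_PAIRS = {"AU", "UA", "GC", "CG"}
WOBBLE_PAIRS = {"GU", "UG"}
CANONICAL_PAIRS = WC_PAIRS | WOBBLE_PAIRS


class MismatchCategory(Enum):
    WC_GU = "WC_GU"
    ONE_MISMATCH = "1_mismatch"
    TWO_MISMATCH = "2_mismatch"
    NOT_IN_REGION = "not_in_region"


def classify_double_mutant(
    region: PairedRegion, g: Genotype, ref: RibozymeReference
) -> MismatchCategory:
    """Categorise an order-2 genotype by how many of the region's pairs it breaks.

    NOT_IN_REGION unless both substituted positions are base-paired
    positions of this region. Otherwise every pair touched by a substitution
    is evaluated after applying the genotype: non-WC, non-wobble pairs are
    mismatches.
    """
    if g.order != 2:
        raise ValueError("mismatch categories are defined for double mutants only")
    positions = region.positions
    if not all(p in positions for p in g.positions):
        return MismatchCategory.NOT_IN_REGION
    mutated = dict(g.substitutions)
    mismatches = 0
    for p5, p3 in region.pairs:
        if p5 in mutated or p3 in mutated:
            b5 = mutated.get(p5, ref.sequence[p5])
            b3 = mutated.get(p3, ref.sequence[p3])
            if b5 + b3 not in CANONICAL_PAIRS:
                mismatches += 1
    return {
        0: MismatchCategory.WC_GU,
        1: MismatchCategory.ONE_MISMATCH,
        2: MismatchCategory.TWO_MISMATCH,
    }[mismatches]


def is_wc_restoring(
    region: PairedRegion, g: Genotype, ref: RibozymeReference
) -> bool:
    """True iff the double sits on the two sides of one pair and yields strict WC."""
    if g.order != 2:
        return False
    (p1, a1), (p2, a2) = g.substitutions
    partner = region.partner
    if partner.get(p1) != p2:
        return False
    b5, b3 = (a1, a2) if p1 < p2 else (a2, a1)
    return b5 + b3 in WC_PAIRS


def on_off_diagonal_split(
    region: PairedRegion,
    records: pd.DataFrame,
    ref: RibozymeReference,
) -> dict:
    """Split in-region epistasis values into WC-restoring vs all other doubles.

    ``records`` is the epistasis table (mut_i, mut_j, epsilon, optionally
    filtered). Returns the two epsilon samples with their means mu_on /
    mu_off (NaN when empty).
    """
    positions = region.positions
    on, off = [], []
    for mut_i, mut_j, eps in zip(records["mut_i"], records["mut_j"], records["epsilon"]):
        g = Genotype.from_string(f"{mut_i},{mut_j}")
        if not all(p in positions for p in g.positions):
            continue
        (on if is_wc_restoring(region, g, ref) else off).append(float(eps))
    return {
        "on": np.array(on),
        "off": np.array(off),
        "mu_on": float(np.mean(on)) if on else float("nan"),
        "mu_off": float(np.mean(off)) if off else float("nan"),
    }


# ---------------------------------------------------------------------------
# Mann-Whitney U

EXACT_LIMIT = 10_000  # switch to the normal approximation above |x|*|y| pairs


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney(x, y, exact_limit: int = EXACT_LIMIT) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two samples.

    Small samples (|x|*|y| <= exact_limit) use full enumeration of all
    C(m+n, m) group assignments of the pooled values, handling ties by the
    midrank (0.5 per tied pair) convention; identical multisets give p = 1
    exactly. Larger samples use the tie-corrected normal approximation with
    continuity correction. Returns (U of x, two-sided p).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("both samples must be non-empty")
    u_obs = _u_statistic(x, y)
    if m * n <= exact_limit and math.comb(m + n, m) <= 200_000:
        pooled = np.concatenate([x, y])
        centre = m * n / 2.0
        dev = abs(u_obs - centre)
        hits = 0
        total = 0
        idx = range(m + n)
        for combo in itertools.combinations(idx, m):
            mask = np.zeros(m + n, dtype=bool)
            mask[list(combo)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u - centre) >= dev - 1e-12:
                hits += 1
            total += 1
        return u_obs, hits / total
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def compare_distributions(x, y) -> tuple[float, float]:
    """Alias of :func:`mann_whitney` named for what the comparison asks."""
    return mann_whitney(x, y)


# ---------------------------------------------------------------------------
# nearest-neighbor duplex free energy

_NN_PATH = Path(__file__).parent / "data" / "nn_stacks_turner2004.tsv"
DUPLEX_INIT = 4.10  # kcal/mol, intermolecular initiation
TERMINAL_AU_GU = 0.50  # per helix end closed by an AU or GU pair
SYMMETRY_CORRECTION = 0.43  # self-complementary duplexes


def _load_stacks() -> dict[str, float]:
    table = {}
    for line in _NN_PATH.read_text().splitlines():
        if not line or line.startswith("#") or line.startswith("stack"):
            continue
        key, dg = line.split("\t")
        table[key] = float(dg)
    return table


STACKS = _load_stacks()


@dataclass(frozen=True)
class RegionEnergy:
    """Nearest-neighbor duplex MFE of one paired region at 37 C."""

    region: str
    delta_g: float
    n_pairs: int
    strand5: str
    strand3: str


def duplex_mfe(region: PairedRegion, ref: RibozymeReference) -> RegionEnergy:
    """delta-G of the region's two strands pairing in register.

    The 5' strand collects the pos5 bases and the 3' strand the pos3 bases
    (outermost-to-innermost); loop nucleotides are excised, so consecutive
    pairs stack directly. delta-G = initiation + sum of nearest-neighbor
    stack terms + terminal AU/GU penalties (+ symmetry correction for a
    self-complementary duplex). A single-pair region gets initiation and
    terminal penalties only.
    """
    if not region.pairs:
        raise ValueError("region has no pairs")
    strand5 = "".join(ref.sequence[p5] for p5, _ in region.pairs)
    strand3 = "".join(ref.sequence[p3] for _, p3 in region.pairs)
    for b5, b3 in zip(strand5, strand3):
        if b5 + b3 not in CANONICAL_PAIRS:
            raise ValueError(
                f"region {region.name}: {b5}:{b3} is not a pairable combination"
            )
    dg = DUPLEX_INIT
    for i in range(len(region.pairs) - 1):
        key = f"{strand5[i]}{strand5[i + 1]}/{strand3[i]}{strand3[i + 1]}"
        dg += STACKS[key]
    for terminal in (strand5[0] + strand3[0], strand5[-1] + strand3[-1]):
        if terminal in {"AU", "UA"} | WOBBLE_PAIRS:
            dg += TERMINAL_AU_GU
    # self-complementary duplex: both strands identical when read 5'->3'
    rev3 = strand3[::-1]
    if strand5 == rev3:
        dg += SYMMETRY_CORRECTION
    return RegionEnergy(
        region=region.name,
        delta_g=round(dg, 2),
        n_pairs=len(region.pairs),
        strand5=strand5,
        strand3=rev3,  # reported 5'->3'
    )


def stability_correlation(
    energies: list[RegionEnergy],
    activity: pd.DataFrame,
    ref: RibozymeReference,
) -> tuple[float, float]:
    """Pearson r (and two-sided p) of median single-mutant RA vs region delta-G."""
    if len(energies) < 3:
        raise ValueError("need at least 3 regions for a correlation")
    medians = []
    for e in energies:
        region = ref.region(e.region)
        ras = median_single_ra(region, activity)
        medians.append(ras)
    x = np.array([e.delta_g for e in energies])
    y = np.array(medians)
    if np.allclose(y, y[0]) or np.allclose(x, x[0]):
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def median_single_ra(region: PairedRegion, activity: pd.DataFrame) -> float:
    """Median mean_RA over all single mutants at the region's paired positions."""
    singles = activity[activity["order"] == 1]
    values = [
        ra
        for g, ra in zip(singles["genotype"], singles["mean_RA"])
        if Genotype.from_string(g).positions[0] in region.positions
    ]
    return float(np.median(values)) if values else float("nan")


# ---------------------------------------------------------------------------
# combined report

def category_table(
    region: PairedRegion,
    records: pd.DataFrame,
    ref: RibozymeReference,
    use_filtered: bool = False,
) -> pd.DataFrame:
    """Epsilon records of in-region doubles with their mismatch category."""
    rows = []
    filtered = records["filtered"] if "filtered" in records else [False] * len(records)
    for mut_i, mut_j, eps, flag in zip(
        records["mut_i"], records["mut_j"], records["epsilon"], filtered
    ):
        if flag and not use_filtered:
            continue
        g = Genotype.from_string(f"{mut_i},{mut_j}")
        cat = classify_double_mutant(region, g, ref)
        if cat is MismatchCategory.NOT_IN_REGION:
            continue
        rows.append((f"{mut_i},{mut_j}", cat.value, float(eps)))
    return pd.DataFrame(rows, columns=["genotype", "category", "epsilon"])


def catalytic_rescue_check(
    activity: pd.DataFrame,
    ref: RibozymeReference,
    rescue_threshold: float = 0.1,
) -> dict:
    """No double mutant touching a catalytic position should exceed the threshold."""
    doubles = activity[activity["order"] == 2]
    rescued = []
    max_ra = 0.0
    n = 0
    for g_str, ra in zip(doubles["genotype"], doubles["mean_RA"]):
        g = Genotype.from_string(g_str)
        if any(p in ref.catalytic_positions for p in g.positions):
            n += 1
            max_ra = max(max_ra, float(ra))
            if ra > rescue_threshold:
                rescued.append(g_str)
    return {
        "n_catalytic_doubles": n,
        "max_RA": max_ra,
        "rescue_threshold": rescue_threshold,
        "rescued": rescued,
    }


def structure_report(
    ref: RibozymeReference,
    activity: pd.DataFrame,
    records: pd.DataFrame,
    rescue_threshold: float = 0.1,
) -> dict:
    """Per-region structural summary: categories, on/off split, delta-G, medians.

    Returns a JSON-serialisable dict; the per-position mean single-mutant RA
    vector and the catalytic rescue check ride along at the top level.
    """
    from .activity import per_position_mean_single_ra

    regions_out = {}
    energies = []
    for region in ref.paired_regions:
        cats = category_table(region, records, ref)
        cat_stats = {
            cat.value: {
                "n": int((cats["category"] == cat.value).sum()),
                "mean_epsilon": float(
                    cats.loc[cats["category"] == cat.value, "epsilon"].mean()
                )
                if (cats["category"] == cat.value).any()
                else None,
            }
            for cat in (
                MismatchCategory.WC_GU,
                MismatchCategory.ONE_MISMATCH,
                MismatchCategory.TWO_MISMATCH,
            )
        }
        split = on_off_diagonal_split(region, records, ref)
        if len(split["on"]) and len(split["off"]):
            u, p = mann_whitney(split["on"], split["off"])
        else:
            u, p = float("nan"), float("nan")
        energy = duplex_mfe(region, ref)
        energies.append(energy)
        regions_out[region.name] = {
            "n_pairs": len(region),
            "categories": cat_stats,
            "mu_on": split["mu_on"],
            "mu_off": split["mu_off"],
            "n_on": int(len(split["on"])),
            "n_off": int(len(split["off"])),
            "mann_whitney_U": u,
            "mann_whitney_p": p,
            "delta_g": energy.delta_g,
            "median_single_RA": median_single_ra(region, activity),
        }

    if len(energies) >= 3:
        r, p = stability_correlation(energies, activity, ref)
    else:
        r, p = float("nan"), float("nan")

    return {
        "reference": ref.name,
        "regions": regions_out,
        "stability_correlation": {"pearson_r": r, "p": p},
        "per_position_mean_single_RA": [
            None if np.isnan(v) else float(v)
            for v in per_position_mean_single_ra(activity, ref)
        ],
        "catalytic_check": catalytic_rescue_check(activity, ref, rescue_threshold),
    }
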