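"""Fraction cleaved, relative activity, replicate averaging, and summaries.

FC = N_clv / (N_clv + N_unclv) per genotype per replicate; RA = FC / FC_wt
with the wild-type FC taken from the same replicate; mean RA is the
arithmetic mean over replicates that pass the depth threshold. RA is not
capped at 1 — super-wild-type activity is representable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference import Genotype, RibozymeReference

log = logging.getLogger(__name__)


def fraction_cleaved(n_clv: int, n_unclv: int) -> float:
    """FC = N_clv/(N_clv+N_unclv); undefined (ValueError) at zero depth."""
    total = n_clv + n_unclv
    if total <= 0:
        raise ValueError("fraction cleaved undefined for zero total reads")
    if n_clv < 0 or n_unclv < 0:
        raise ValueError("counts must be non-negative")
    return n_clv / total


def relative_activity(fc: float, fc_wt: float) -> float:
    """RA = FC/FC_wt; requires a cleaving wild type in that replicate."""
    if fc_wt <= 0:
        raise ValueError("wild-type FC must be > 0 to normalize a replicate")
    return fc / fc_wt


def activity_table(
    counts: pd.DataFrame,
    min_reads: int = 10,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-genotype activity from a counts table.

    ``counts`` columns: genotype, replicate, n_cleaved, n_uncleaved.
    Default mode computes FC and RA per replicate and averages RA across the
    replicates where the genotype has at least ``min_reads`` reads (the
    wording "averaged across the three replicates"). ``pooled=True`` instead
    sums counts over replicates before a single FC/RA — the depth-starved
    alternative for sparsely observed doubles.

    Returns columns: genotype, order, mean_RA, mean_FC, total_reads,
    n_replicates_used, plus per-replicate FC_<rep>/RA_<rep> in default mode.
    Genotypes with no usable replicate are excluded and logged.
    """
    required = {"genotype", "replicate", "n_cleaved", "n_uncleaved"}
    if not required <= set(counts.columns):
        raise ValueError(f"counts table must have columns {sorted(required)}")

    if pooled:
        agg = counts.groupby("genotype", sort=False)[
            ["n_cleaved", "n_uncleaved"]
        ].sum()
        total = agg["n_cleaved"] + agg["n_uncleaved"]
        keep = total >= max(min_reads, 1)
        dropped = (~keep).sum()
        if dropped:
            log.info("excluding %d genotypes below %d pooled reads", dropped, min_reads)
        agg = agg[keep]
        if "WT" not in agg.index:
            raise ValueError("wild type absent from counts; cannot normalize")
        fc = agg["n_cleaved"] / (agg["n_cleaved"] + agg["n_uncleaved"])
        fc_wt = fc.loc["WT"]
        out = pd.DataFrame(
            {
                "genotype": agg.index,
                "mean_FC": fc.values,
                "mean_RA": (fc / fc_wt).values,
                "total_reads": (agg["n_cleaved"] + agg["n_uncleaved"]).values,
                "n_replicates_used": counts.groupby("genotype", sort=False)[
                    "replicate"
                ].nunique().reindex(agg.index).values,
            }
        ).reset_index(drop=True)
    else:
        wide_c = counts.pivot_table(
            index="genotype", columns="replicate", values="n_cleaved",
            aggfunc="sum", fill_value=0,
        )
        wide_u = counts.pivot_table(
            index="genotype", columns="replicate", values="n_uncleaved",
            aggfunc="sum", fill_value=0,
        )
        reps = list(wide_c.columns)
        if "WT" not in wide_c.index:
            raise ValueError("wild type absent from counts; cannot normalize")
        totals = wide_c + wide_u
        fc = wide_c / totals.where(totals > 0)
        for rep in reps:
            wt_fc = fc.loc["WT", rep]
            if not wt_fc > 0:
                raise ValueError(f"wild-type FC is 0 in {rep}; replicate unusable")
        ra = fc / fc.loc["WT"]
        usable = totals >= max(min_reads, 1)
        ra_masked = ra.where(usable)
        n_used = usable.sum(axis=1)
        keep = n_used > 0
        dropped = (~keep).sum()
        if dropped:
            log.info(
                "excluding %d genotypes with <%d reads in every replicate",
                dropped, min_reads,
            )
        out = pd.DataFrame(
            {
                "genotype": fc.index,
                "mean_FC": fc.where(usable).mean(axis=1).values,
                "mean_RA": ra_masked.mean(axis=1).values,
                "total_reads": totals.sum(axis=1).values,
                "n_replicates_used": n_used.values,
            }
        )
        for rep in reps:
            out[f"FC_{rep}"] = fc[rep].values
            out[f"RA_{rep}"] = ra[rep].values
        out = out[keep.values].reset_index(drop=True)

    out.insert(1, "order", [Genotype.from_string(g).order for g in out["genotype"]])
    return out


def per_position_mean_single_ra(
    table: pd.DataFrame, ref: RibozymeReference
) -> np.ndarray:
    """Position p -> mean of mean_RA over the three single mutants at p.

    Positions with no observed single mutant are NaN.
    """
    vec = np.full(ref.length, np.nan)
    singles = table[table["order"] == 1]
    by_pos: dict[int, list[float]] = {}
    for g, ra in zip(singles["genotype"], singles["mean_RA"]):
        pos = Genotype.from_string(g).positions[0]
        by_pos.setdefault(pos, []).append(ra)
    for pos, values in by_pos.items():
        vec[pos] = float(np.mean(values))
    return vec


@dataclass(frozen=True)
class MutantClassFC:
    """Class-average fraction cleaved, as in a per-ribozyme summary row."""

    wt_fc: float
    single_mean_fc: float
    double_mean_fc: float


def mutant_class_average_fc(table: pd.DataFrame) -> MutantClassFC:
    """Unweighted means of replicate-mean FC for wt / singles / doubles."""
    wt = table.loc[table["order"] == 0, "mean_FC"]
    singles = table.loc[table["order"] == 1, "mean_FC"]
    doubles = table.loc[table["order"] == 2, "mean_FC"]
    return MutantClassFC(
        wt_fc=float(wt.iloc[0]) if len(wt) else float("nan"),
        single_mean_fc=float(singles.mean()) if len(singles) else float("nan"),
        double_mean_fc=float(doubles.mean()) if len(doubles) else float("nan"),
    )
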