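"""Pairwise epistasis from double-mutant relative activities.

epsilon = log( RA_ij / (RA_i * RA_j) ), natural log by default; zero is the
additivity point on the multiplicative scale, positive values mean the
double mutant is more active than the product of its singles predicts
(compensatory pairs), negative values less. A small floor keeps the log
finite when an RA estimate is exactly zero. A sigma-based filter flags
records where the double's RA is too close to either single's RA relative
to the spread of all such differences (false-positive guard).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .reference import Genotype, RibozymeReference

log = logging.getLogger(__name__)

DEFAULT_FLOOR = 1e-3


def epistasis_value(
    ra_i: float,
    ra_j: float,
    ra_ij: float,
    floor: float = DEFAULT_FLOOR,
    base: float = math.e,
) -> float:
    """epsilon = log(max(RA_ij,floor) / (max(RA_i,floor) * max(RA_j,floor)))."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    if min(ra_i, ra_j, ra_ij) < 0:
        raise ValueError("relative activities must be non-negative")
    value = math.log(max(ra_ij, floor) / (max(ra_i, floor) * max(ra_j, floor)))
    if base != math.e:
        value /= math.log(base)
    return value


def epistasis_table(
    activity: pd.DataFrame,
    floor: float = DEFAULT_FLOOR,
    base: float = math.e,
) -> pd.DataFrame:
    """One EpistasisRecord per observed double whose both singles are observed.

    ``activity`` is the table from :func:`ribodms.activity.activity_table`
    (replicate-mean RA by default). Returns columns mut_i, mut_j, RA_i,
    RA_j, RA_ij, epsilon.
    """
    ra = dict(zip(activity["genotype"], activity["mean_RA"]))
    rows = []
    doubles = activity[activity["order"] == 2]
    for g_str, ra_ij in zip(doubles["genotype"], doubles["mean_RA"]):
        g = Genotype.from_string(g_str)
        (p1, a1), (p2, a2) = g.substitutions
        mi, mj = f"{p1}:{a1}", f"{p2}:{a2}"
        if mi not in ra or mj not in ra:
            continue
        ra_i, ra_j = ra[mi], ra[mj]
        rows.append(
            (
                mi,
                mj,
                ra_i,
                ra_j,
                ra_ij,
                epistasis_value(ra_i, ra_j, ra_ij, floor=floor, base=base),
            )
        )
    return pd.DataFrame(
        rows, columns=["mut_i", "mut_j", "RA_i", "RA_j", "RA_ij", "epsilon"]
    )


def filter_epistasis(
    records: pd.DataFrame,
    c: float = 1.0,
    combiner: str = "either",
) -> pd.DataFrame:
    """Flag records whose double-vs-single RA differences are within c·sigma.

    sigma is the standard deviation of the pooled distribution of
    differences RA_ij - RA_k over all records and both constituent singles.
    With ``combiner='either'`` (default) a record is flagged when either
    |RA_ij - RA_i| or |RA_ij - RA_j| falls below c·sigma; ``'both'``
    requires both. Flagged epsilons are set aside as unreliable, not
    altered. Adds columns ``sigma_used`` and ``filtered``.
    """
    if combiner not in ("either", "both"):
        raise ValueError("combiner must be 'either' or 'both'")
    out = records.copy()
    d_i = out["RA_ij"] - out["RA_i"]
    d_j = out["RA_ij"] - out["RA_j"]
    diffs = np.concatenate([d_i.to_numpy(float), d_j.to_numpy(float)])
    if diffs.size < 2:
        log.warning("fewer than 2 differences; sigma undefined, nothing filtered")
        out["sigma_used"] = np.nan
        out["filtered"] = False
        return out
    sigma = float(np.std(diffs, ddof=1))
    near_i = d_i.abs() < c * sigma
    near_j = d_j.abs() < c * sigma
    out["sigma_used"] = sigma
    out["filtered"] = (near_i | near_j) if combiner == "either" else (near_i & near_j)
    return out


class HeatmapMatrix:
    """Dense 3L x 3L matrix of double-mutant mean RA.

    Axes are position-major with alternatives in fixed A<C<G<U order
    (reference base skipped); the diagonal holds single-mutant RA;
    same-position off-diagonal cells are impossible genotypes and stay NaN,
    as do unobserved doubles.
    """

    def __init__(self, ref: RibozymeReference):
        self.ref = ref
        self.labels = [
            f"{pos}:{alt}" for pos in range(ref.length) for alt in ref.alternatives(pos)
        ]
        self.index = {lab: i for i, lab in enumerate(self.labels)}
        n = len(self.labels)
        self.values = np.full((n, n), np.nan)

    @property
    def fill_fraction(self) -> float:
        """Filled fraction of the structurally valid cells."""
        L = self.ref.length
        valid = 9 * L * (L - 1) + 3 * L  # off-diagonal (ordered) + diagonal
        return float(np.count_nonzero(~np.isnan(self.values))) / valid

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def build_heatmap_matrix(
    activity: pd.DataFrame, ref: RibozymeReference
) -> HeatmapMatrix:
    """Fill the pairwise RA matrix from an activity table (symmetric)."""
    hm = HeatmapMatrix(ref)
    for g_str, ra, order in zip(
        activity["genotype"], activity["mean_RA"], activity["order"]
    ):
        if order == 1:
            i = hm.index[g_str]
            hm.values[i, i] = ra
        elif order == 2:
            g = Genotype.from_string(g_str)
            (p1, a1), (p2, a2) = g.substitutions
            i, j = hm.index[f"{p1}:{a1}"], hm.index[f"{p2}:{a2}"]
            hm.values[i, j] = ra
            hm.values[j, i] = ra
    return hm
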