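"""End-to-end drivers: simulate -> count -> activity -> epistasis -> structure.

These functions tie the stages together exactly as the analysis scripts and
the acceptance checks run them, so every reported number comes from the same
code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .activity import activity_table, mutant_class_average_fc
from .epistasis import epistasis_table, filter_epistasis
from .reads import count_replicates
from .reference import Genotype, RibozymeReference
from .simulate import (
    ActivityModel,
    SimulationConfig,
    assign_ground_truth,
    emit_reads,
)
from .structure import (
    MismatchCategory,
    category_table,
    is_wc_restoring,
    mann_whitney,
    structure_report,
)


@dataclass
class EndToEndResult:
    counts: pd.DataFrame
    reports: dict
    activity: pd.DataFrame
    epistasis: pd.DataFrame
    truth: pd.DataFrame
    report: dict
    metrics: dict


def wc_restoring_pairs(ref: RibozymeReference) -> list[Genotype]:
    """All planted compensatory doubles: partner-position, each single breaks,
    double restores a strict Watson-Crick pair."""
    out = []
    for region in ref.paired_regions:
        for p5, p3 in region.pairs:
            ref5, ref3 = ref.sequence[p5], ref.sequence[p3]
            for a5 in ref.alternatives(p5):
                for a3 in ref.alternatives(p3):
                    g = Genotype(((p5, a5), (p3, a3)))
                    if is_wc_restoring(region, g, ref):
                        from .structure import CANONICAL_PAIRS

                        if (
                            a5 + ref3 not in CANONICAL_PAIRS
                            and ref5 + a3 not in CANONICAL_PAIRS
                        ):
                            out.append(g)
    return out


def run_end_to_end(
    ref: RibozymeReference,
    model: ActivityModel,
    config: SimulationConfig,
    workdir: str | Path,
    pooled: bool = True,
    min_reads: int = 1,
    filter_c: float = 1.0,
) -> EndToEndResult:
    """Simulate a full run and push it through the complete analysis.

    Pooled counts with min_reads=1 are the defaults here because a
    desk-scale run leaves double mutants with a handful of reads each;
    see the methods note.
    """
    workdir = Path(workdir)
    truth = assign_ground_truth(ref, model)
    manifest = emit_reads(ref, truth, config, workdir, model=model)
    counts, reports = count_replicates(manifest["fastq"], ref)
    act = activity_table(counts, min_reads=min_reads, pooled=pooled)
    eps = filter_epistasis(epistasis_table(act), c=filter_c)
    rep = structure_report(ref, act, eps)
    metrics = compute_recovery_metrics(ref, truth, counts, act, eps)
    return EndToEndResult(
        counts=counts,
        reports={k: v.to_dict() for k, v in reports.items()},
        activity=act,
        epistasis=eps,
        truth=truth,
        report=rep,
        metrics=metrics,
    )


def compute_recovery_metrics(
    ref: RibozymeReference,
    truth: pd.DataFrame,
    counts: pd.DataFrame,
    act: pd.DataFrame,
    eps: pd.DataFrame,
) -> dict:
    """Coverage, RA recovery error, and compensatory-pair epsilon summaries."""
    observed = set(counts["genotype"])
    singles = truth[truth["order"] == 1]["genotype"]
    doubles = truth[truth["order"] == 2]["genotype"]
    cov_singles = float(np.mean([g in observed for g in singles]))
    cov_doubles = float(np.mean([g in observed for g in doubles]))

    true_ra = dict(zip(truth["genotype"], truth["true_ra"]))
    est = act[act["order"] == 1]
    errs = [
        est_ra - true_ra[g]
        for g, est_ra in zip(est["genotype"], est["mean_RA"])
        if g in true_ra
    ]
    rmse_singles = float(np.sqrt(np.mean(np.square(errs)))) if errs else float("nan")

    comp = wc_restoring_pairs(ref)
    comp_keys = {str(g) for g in comp}
    eps_by_pair = {
        f"{mi},{mj}": (e, f)
        for mi, mj, e, f in zip(
            eps["mut_i"], eps["mut_j"], eps["epsilon"],
            eps.get("filtered", pd.Series([False] * len(eps))),
        )
    }
    comp_eps = [eps_by_pair[k] for k in comp_keys if k in eps_by_pair]
    n_comp_obs = len(comp_eps)
    comp_positive = sum(e > 0 for e, _ in comp_eps)
    comp_surviving = sum((e > 0) and (not f) for e, f in comp_eps)

    wt_row = act[act["order"] == 0]
    fc_classes = mutant_class_average_fc(act)
    return {
        "coverage_singles": cov_singles,
        "coverage_doubles": cov_doubles,
        "n_singles_possible": int(len(singles)),
        "n_doubles_possible": int(len(doubles)),
        "rmse_single_ra": rmse_singles,
        "n_compensatory_planted": len(comp),
        "n_compensatory_observed": n_comp_obs,
        "n_compensatory_eps_positive": int(comp_positive),
        "n_compensatory_surviving_filter": int(comp_surviving),
        "wt_fc_estimate": float(wt_row["mean_FC"].iloc[0]) if len(wt_row) else float("nan"),
        "wt_reads": int(wt_row["total_reads"].iloc[0]) if len(wt_row) else 0,
        "class_fc": {
            "wt": fc_classes.wt_fc,
            "singles": fc_classes.single_mean_fc,
            "doubles": fc_classes.double_mean_fc,
        },
    }


def per_stem_category_ordering(
    ref: RibozymeReference, eps: pd.DataFrame
) -> dict:
    """Per region: mean epsilon by category and MW p between adjacent categories."""
    out = {}
    for region in ref.paired_regions:
        cats = category_table(region, eps, ref, use_filtered=True)
        sub = {
            c.value: cats.loc[cats["category"] == c.value, "epsilon"].to_numpy()
            for c in (
                MismatchCategory.WC_GU,
                MismatchCategory.ONE_MISMATCH,
                MismatchCategory.TWO_MISMATCH,
            )
        }
        entry = {
            f"mean_{k}": (float(np.mean(v)) if len(v) else float("nan"))
            for k, v in sub.items()
        }
        for a, b in (("WC_GU", "1_mismatch"), ("1_mismatch", "2_mismatch")):
            if len(sub[a]) and len(sub[b]):
                _, p = mann_whitney(sub[a], sub[b])
            else:
                p = float("nan")
            entry[f"p_{a}_vs_{b}"] = p
        entry["ordered"] = (
            entry["mean_WC_GU"] > entry["mean_1_mismatch"] > entry["mean_2_mismatch"]
            if not any(
                math.isnan(entry[f"mean_{k}"])
                for k in ("WC_GU", "1_mismatch", "2_mismatch")
            )
            else False
        )
        out[region.name] = entry
    return out
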