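"""Variant-call and classify every read; aggregate cleaved/uncleaved counts.

Consumes the FASTQs of a simulated (or real, pre-merged) run, assigns each
read a genotype with the sequence-length sliding window, classifies it by
the presence of the 5' leader, and writes the per-genotype counts table
plus a mapping report.
"""

import json
from pathlib import Path

import click

from ribodms.reads import count_replicates
from ribodms.reference import load_builtin


@click.command()
@click.option("--ribozyme", default="twister", show_default=True)
@click.option("--run-dir", default=None, help="default scratch/run_<name>")
@click.option("--out-dir", default="results", show_default=True)
def main(ribozyme, run_dir, out_dir):
    ref = load_builtin(ribozyme)
    run_dir = Path(run_dir or f"scratch/run_{ribozyme}")
    fastqs = sorted(run_dir.glob("reads_rep*.fastq"))
    if not fastqs:
        raise click.ClickException(f"no FASTQs under {run_dir}; run 01_simulate_library.py")
    counts, reports = count_replicates(fastqs, ref)
    out = Path(out_dir)
    out.mkdir(exist_ok=True)
    counts_path = out / f"counts_{ribozyme}.tsv"
    counts.to_csv(counts_path, sep="\t", index=False)
    report = {k: v.to_dict() for k, v in reports.items()}
    (out / f"mapping_report_{ribozyme}.json").write_text(json.dumps(report, indent=2))
    total = sum(r["total"] for r in report.values())
    mapped = sum(r["mapped"] for r in report.values())
    click.echo(f"{total} reads, {mapped} mapped to <=2 mutations ({100*mapped/total:.1f}%)")
    click.echo(f"counts: {counts_path} ({counts['genotype'].nunique()} genotypes)")


if __name__ == "__main__":
    main()
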