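"""End-to-end pipeline on synthetic data: simulate, call, filter, flank, report.

One function call runs the whole marker-selection workflow against a seeded
synthetic cross and writes every artefact (FASTA reference, truth table,
repeat BED, per-parent pileups and calls, panel VCF, audit table, assay
FASTA, density report) under an output directory.  All outputs are
byte-deterministic in the configuration seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from . import flanks as flanks_mod
from . import genotypes, io, report as report_mod, simgenome, snpfilter


@dataclasses.dataclass
class PipelineResult:
    """In-memory handles to everything the pipeline produced."""

    reference: io.ReferenceSet
    truth: list[simgenome.TruthRecord]
    calls: dict[str, pd.DataFrame]
    panel: pd.DataFrame
    audit: pd.DataFrame
    flank_records: list
    density: report_mod.DensityReport
    outdir: Path | None


def run_pipeline(
    sim_cfg: simgenome.SimConfig,
    filter_cfg: snpfilter.FilterConfig | None = None,
    outdir: str | Path | None = None,
    k: int = flanks_mod.DEFAULT_K,
    call_error_rate: float | None = None,
) -> PipelineResult:
    """Run simulate -> call -> cascade -> flanks -> report.

    The density report is computed over the cascade-retained panel; the assay
    FASTA contains only markers whose 121-base context also passes the k-mer
    uniqueness screen.  ``call_error_rate`` defaults to the simulation's
    error rate (or 0.01 for a noise-free simulation, since the genotype model
    needs a positive miscall rate).
    """
    sim_cfg.validate()
    filter_cfg = filter_cfg or snpfilter.FilterConfig()
    filter_cfg.validate()
    if call_error_rate is None:
        call_error_rate = sim_cfg.error_rate if sim_cfg.error_rate > 0 else 0.01

    ref = simgenome.simulate_reference(sim_cfg)
    truth = simgenome.spike_variants(ref, sim_cfg)
    pileups = {
        parent: simgenome.simulate_pileup(ref, truth, sim_cfg, parent)
        for parent in sim_cfg.parents
    }
    calls = {
        parent: genotypes.call_table(pileup, error_rate=call_error_rate)
        for parent, pileup in pileups.items()
    }
    panel, audit = snpfilter.run_cascade(calls, None, ref.repeats, ref, filter_cfg)

    flank_records, edge_drops = flanks_mod.extract_flanks(ref, panel)
    flanks_mod.screen_flanks(flank_records, ref, k)
    unique_records = [r for r in flank_records if r.unique]

    density = report_mod.density_report(panel, ref.lengths)

    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        io.write_fasta(ref, out / "reference.fa")
        io.write_bed(ref.repeats, out / "repeats.bed")
        simgenome.write_truth(truth, out / "truth.tsv")
        with open(out / "scaffolds.tsv", "w") as fh:
            for name, length in ref.lengths.items():
                fh.write(f"{name}\t{length}\n")
        for parent in sim_cfg.parents:
            io.write_pileup(pileups[parent], out / f"pileup.{parent}.tsv")
            io.write_calls(calls[parent], out / f"calls.{parent}.tsv")
        audit_vcf = audit.copy()
        io.write_vcf(
            audit_vcf, out / "panel.vcf",
            contig_lengths=ref.lengths,
            filter_names=snpfilter.FILTER_ORDER + [snpfilter.TRIALLELIC],
        )
        audit.to_csv(out / "audit.tsv", sep="\t", index=False)
        flanks_mod.export_assay_fasta(unique_records, out / "assay.fa")
        flanks_mod.export_consensus_fasta(unique_records, out / "consensus.fa")
        flanks_mod.flank_table(flank_records).to_csv(
            out / "flanks.tsv", sep="\t", index=False
        )
        if len(edge_drops):
            edge_drops.to_csv(out / "flank_drops.tsv", sep="\t", index=False)
        report_mod.write_report_tsv(density, out / "report.tsv")

    return PipelineResult(
        reference=ref, truth=truth, calls=calls, panel=panel, audit=audit,
        flank_records=flank_records, density=density, outdir=out,
    )
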