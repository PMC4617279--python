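"""End-to-end orchestration: simulate → detect → annotate → quantify,
with a per-sample run summary mirroring the published sequencing-summary
columns (total reads, %rRNA, linear-junction reads, head-to-tail reads,
percentage head-to-tail of linear, candidate count).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import alignment_core as ac
from . import annotation as ann
from . import io_formats as io
from . import junction_discovery as jd
from . import quantification as quant
from . import synthetic_data as sim
from .config import DetectionConfig, QuantConfig

log = logging.getLogger(__name__)


@dataclass
class RunSummary:
    sample: str
    total_reads: int
    pct_rrna: float
    linear_junction_reads: int
    head_to_tail_reads: int
    pct_head_to_tail_of_linear: float
    n_candidates: int

    def to_row(self) -> dict:
        return {
            "sample": self.sample,
            "total_reads": self.total_reads,
            "pct_rrna": round(self.pct_rrna, 4),
            "linear_junction_reads": self.linear_junction_reads,
            "head_to_tail_reads": self.head_to_tail_reads,
            "pct_head_to_tail_of_linear": round(self.pct_head_to_tail_of_linear, 4),
            "n_candidates": self.n_candidates,
        }


@dataclass
class PipelineResult:
    summary: RunSummary
    candidates: list
    annotated: list
    linear_junctions: pd.DataFrame
    linear_calls: list
    ratios: pd.DataFrame
    gene_tpm: pd.DataFrame
    circ_expression: pd.DataFrame
    truth: Optional[sim.SimTruth] = None
    counters: dict = field(default_factory=dict)


def fold_difference(summary_a: RunSummary, summary_b: RunSummary) -> float:
    """Ratio of the two samples' percent-head-to-tail-of-linear values.

    A zero denominator is reported as infinity (flagged by the caller's
    formatting, not an error)."""
    if summary_b.pct_head_to_tail_of_linear == 0:
        return float("inf")
    return summary_a.pct_head_to_tail_of_linear / summary_b.pct_head_to_tail_of_linear


def run_pipeline(
    reads: list[io.ReadRecord],
    genome: io.Genome,
    models: list[io.GeneModel],
    rrna: Optional[io.Genome] = None,
    det_cfg: Optional[DetectionConfig] = None,
    quant_cfg: Optional[QuantConfig] = None,
    sample: str = "sample",
    out_dir: Optional[str] = None,
) -> PipelineResult:
    """Run detection → annotation → quantification over in-memory inputs.

    When ``out_dir`` is given, all stage outputs are written there as TSV /
    BED with a config-hash header (no timestamps, so reruns are
    byte-identical)."""
    det_cfg = det_cfg or DetectionConfig()
    quant_cfg = quant_cfg or QuantConfig()
    total = len(reads)

    genome_index = ac.build_index(genome, det_cfg.seed_k)
    rrna_index = ac.build_index(rrna, det_cfg.seed_k) if rrna is not None else None

    kept, frac_rrna = ac.fraction_rrna(reads, rrna_index, det_cfg.rrna_mismatches)
    log.info("stage=rrna_screen in=%d out=%d removed_frac=%.4f", total, len(kept), frac_rrna)

    unmapped, contiguous = ac.drop_contiguous(kept, genome_index, det_cfg.contiguous_mismatches)
    log.info("stage=contiguous_screen in=%d unmapped=%d mapped=%d",
             len(kept), len(unmapped), len(contiguous))

    disc = jd.discover(unmapped, genome_index, det_cfg)
    log.info("stage=discovery in=%d candidates=%d", len(unmapped), len(disc.candidates))

    annotated = ann.annotate(disc.candidates, models)
    gene_hits, pc_mapped = quant.count_gene_hits(contiguous, models)
    tpm = quant.gene_tpm(gene_hits, models)
    circ_counts = {f"{c.contig}:{c.start}-{c.end}:{c.strand}": c.n_reads
                   for c in disc.candidates}
    normalized = (
        quant.normalize_circ(circ_counts, pc_mapped, quant_cfg) if pc_mapped else
        {k: float("nan") for k in circ_counts}
    )
    circ_expr = pd.DataFrame(
        [
            {
                "key": f"{c.contig}:{c.start}-{c.end}:{c.strand}",
                "contig": c.contig, "start": c.start, "end": c.end,
                "strand": c.strand, "n_reads": c.n_reads, "n_unique": c.n_unique,
                "normalized": normalized[f"{c.contig}:{c.start}-{c.end}:{c.strand}"],
            }
            for c in disc.candidates
        ],
        columns=["key", "contig", "start", "end", "strand", "n_reads",
                 "n_unique", "normalized"],
    )
    ratios, n_excluded = quant.ratio_table(annotated, disc.linear_junctions, models, quant_cfg)
    log.info("stage=quantify ratios=%d excluded_junctionless=%d", len(ratios), n_excluded)

    linear_reads = int(disc.linear_junctions["n_reads"].sum()) if len(disc.linear_junctions) else 0
    ht_reads = sum(c.n_reads for c in disc.candidates)
    pct_ht = 100.0 * ht_reads / linear_reads if linear_reads else 0.0
    summary = RunSummary(
        sample=sample,
        total_reads=total,
        pct_rrna=100.0 * frac_rrna,
        linear_junction_reads=linear_reads,
        head_to_tail_reads=ht_reads,
        pct_head_to_tail_of_linear=pct_ht,
        n_candidates=len(disc.candidates),
    )

    result = PipelineResult(
        summary, disc.candidates, annotated, disc.linear_junctions,
        disc.linear_calls, ratios, tpm, circ_expr, counters=dict(disc.counters),
    )
    if out_dir:
        write_outputs(result, disc, det_cfg, out_dir)
    return result


def write_outputs(result: PipelineResult, disc, det_cfg: DetectionConfig, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    h = det_cfg.config_hash()
    io.write_bed(result.candidates, os.path.join(out_dir, "circ_candidates.bed"), h)
    result.linear_junctions.to_csv(
        os.path.join(out_dir, "linear_junctions.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [{"read_id": r.read_id, "reason": r.reason} for r in disc.rejections],
        columns=["read_id", "reason"],
    ).to_csv(os.path.join(out_dir, "rejected_reads.tsv"), sep="\t", index=False)
    result.gene_tpm.to_csv(os.path.join(out_dir, "gene_tpm.tsv"), sep="\t", index=False)
    result.circ_expression.to_csv(
        os.path.join(out_dir, "circ_expression.tsv"), sep="\t", index=False)
    result.ratios.to_csv(os.path.join(out_dir, "ratios.tsv"), sep="\t", index=False)
    pd.DataFrame([result.summary.to_row()]).to_csv(
        os.path.join(out_dir, "run_summary.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "counters.json"), "w") as fh:
        json.dump(result.counters, fh, indent=1, sort_keys=True)


def run_simulated(
    sim_cfg: sim.SimConfig,
    det_cfg: Optional[DetectionConfig] = None,
    quant_cfg: Optional[QuantConfig] = None,
    sample: str = "sim",
    out_dir: Optional[str] = None,
) -> PipelineResult:
    """Simulate a sample and push it through the full pipeline."""
    genome, models = sim.build_genome(sim_cfg)
    rrna = sim.build_rrna(sim_cfg) if sim_cfg.rrna_fraction > 0 else None
    reads, truth = sim.simulate_reads(genome, models, sim_cfg, rrna)
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        io.write_fasta(genome, os.path.join(out_dir, "genome.fa"))
        if rrna is not None:
            io.write_fasta(rrna, os.path.join(out_dir, "rrna.fa"))
        io.write_gtf(models, os.path.join(out_dir, "genes.gtf"))
        io.write_fastq(reads, os.path.join(out_dir, "reads.fastq"))
        sim.write_truth(truth, os.path.join(out_dir, "truth.tsv"))
    result = run_pipeline(
        reads, genome, models, rrna, det_cfg, quant_cfg, sample=sample, out_dir=out_dir
    )
    result.truth = truth
    return result
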