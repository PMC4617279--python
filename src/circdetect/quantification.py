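"""Expression quantification: normalized circRNA counts, host-gene TPM and
circular-to-linear ratios.

circRNA expression is the raw head-to-tail read count, normalized between
samples by dividing by the number of reads mapping to protein-coding gene
regions and multiplying by one million.  Host-gene expression uses TPM
(reads per kilobase of spliced gene length, renormalized to sum to 1e6).
The circular-to-linear ratio of a circle is

    (head-to-tail reads + 1) / (median linear junction reads of the host + 1)

with the median taken over all annotated splice junctions of the host gene
(undetected junctions contribute zero), and circles from junctionless host
genes excluded.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .alignment_core import Alignment
from .io_formats import GeneModel
from .quant_types import ExpressionRecord, RatioRecord  # noqa: F401  (re-export)
from .config import QuantConfig

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# read→gene counting (union mode over exons)
# ---------------------------------------------------------------------------

def count_gene_hits(
    alignments: Sequence[Alignment], models: Sequence[GeneModel]
) -> tuple[dict[str, int], int]:
    """(per-gene read counts, protein-coding-mapped read count).

    A read counts for a gene when its end-to-end alignment overlaps an exon
    of exactly one gene (union-mode contract; reads touching exons of two
    or more genes are discarded).  The second value counts reads whose
    alignment overlaps any protein-coding exon — the per-million
    denominator for circRNA normalization.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    biotype = {g.gene_id: g.biotype for g in models}
    for g in models:
        for s, e in g.exon_union():
            trees[g.contig][s:e] = g.gene_id
    counts: dict[str, int] = defaultdict(int)
    pc_mapped = 0
    for a in alignments:
        gids = {iv.data for iv in trees.get(a.contig, IntervalTree())[a.start : a.end]}
        if any(biotype[g] == "protein_coding" for g in gids):
            pc_mapped += 1
        if len(gids) == 1:
            counts[gids.pop()] += 1
    return dict(counts), pc_mapped


def normalize_circ(
    counts: dict, protein_coding_mapped: int, cfg: Optional[QuantConfig] = None
) -> dict:
    """Reads-per-million-protein-coding-mapped normalization."""
    cfg = cfg or QuantConfig()
    if protein_coding_mapped <= 0:
        raise ValueError("protein_coding_mapped must be positive")
    return {k: v / protein_coding_mapped * cfg.per_million for k, v in counts.items()}


def gene_tpm(read_gene_hits: dict, models: Sequence[GeneModel]) -> pd.DataFrame:
    """TPM per gene from union-exon lengths.

    rate_g = count_g / spliced-length-in-kb; TPM_g = rate_g / Σrate × 1e6.
    All-zero counts yield all-zero TPM.
    """
    rows = []
    for g in models:
        count = read_gene_hits.get(g.gene_id, 0)
        kb = g.union_length() / 1000.0
        rows.append({"gene_id": g.gene_id, "count": count, "length_kb": kb,
                     "rate": count / kb})
    df = pd.DataFrame(rows)
    total = df["rate"].sum()
    df["tpm"] = 0.0 if total == 0 else df["rate"] / total * 1e6
    return df[["gene_id", "count", "length_kb", "tpm"]]


# ---------------------------------------------------------------------------
# circular-to-linear ratios
# ---------------------------------------------------------------------------

def linear_junction_counts(linear_table: pd.DataFrame) -> dict[tuple, int]:
    return {
        (r.contig, r.strand, int(r.donor_pos), int(r.acceptor_pos)): int(r.n_reads)
        for r in linear_table.itertuples()
    }


def circ_linear_ratio(
    head_to_tail_reads: int,
    host_gene: GeneModel,
    detected_linear: dict[tuple, int],
    cfg: Optional[QuantConfig] = None,
    circ_id: str = "",
) -> Optional[RatioRecord]:
    """Ratio record for one circle, or None if the host is junctionless.

    The median runs over every annotated junction of the host gene; a
    junction absent from the detected table contributes zero (the
    ``detected_only`` switch restricts to detected junctions instead).
    """
    cfg = cfg or QuantConfig()
    annotated = host_gene.junctions()
    if not annotated:
        return None
    per_junction = [
        detected_linear.get((host_gene.contig, host_gene.strand, d, a), 0)
        for d, a in annotated
    ]
    if cfg.detected_only:
        per_junction = [c for c in per_junction if c > 0] or [0]
    med = float(np.median(per_junction))
    ratio = (head_to_tail_reads + cfg.pseudocount) / (med + cfg.pseudocount)
    return RatioRecord(circ_id, head_to_tail_reads, med, ratio)


def ratio_table(
    annotated_circles,
    linear_table: pd.DataFrame,
    models: Sequence[GeneModel],
    cfg: Optional[QuantConfig] = None,
) -> tuple[pd.DataFrame, int]:
    """Ratios for all annotated candidates with a junction-bearing host.

    Returns (table, n_excluded) where exclusions count circles whose host
    gene is missing or has no annotated splice junction.
    """
    cfg = cfg or QuantConfig()
    by_id = {g.gene_id: g for g in models}
    detected = linear_junction_counts(linear_table)
    rows = []
    excluded = 0
    for a in annotated_circles:
        cand = a.candidate
        if a.host_gene is None or a.host_gene not in by_id:
            excluded += 1
            continue
        rec = circ_linear_ratio(
            cand.n_reads, by_id[a.host_gene], detected, cfg,
            circ_id=f"{cand.contig}:{cand.start}-{cand.end}:{cand.strand}",
        )
        if rec is None:
            excluded += 1
            continue
        rows.append({
            "circ_id": rec.circ_id, "host_gene": a.host_gene,
            "head_to_tail_reads": rec.head_to_tail_reads,
            "median_linear_reads": rec.median_linear_reads,
            "ratio": rec.ratio,
        })
    cols = ["circ_id", "host_gene", "head_to_tail_reads", "median_linear_reads", "ratio"]
    return pd.DataFrame(rows, columns=cols), excluded


def ratio_fractions(ratios: Sequence[float]) -> dict[str, float]:
    """Fraction of circles more expressed than their linear isoforms
    (ratio > 1) and strongly so (ratio > 4)."""
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size == 0:
        return {"gt1": float("nan"), "gt4": float("nan")}
    return {
        "gt1": float((arr > 1).mean()),
        "gt4": float((arr > 4).mean()),
    }


# ---------------------------------------------------------------------------
# cross-sample summaries
# ---------------------------------------------------------------------------

def cross_sample_summary(samples: dict[str, pd.DataFrame]) -> dict:
    """Overlap counts, Spearman rho and ECDF data for ≥2 samples.

    Each sample table must carry columns ``key`` (junction identifier),
    ``n_reads``, ``n_unique`` and ``normalized``.  Overlaps are reported at
    the two published thresholds (shared with >5 reads in both samples;
    shared with ≥2 unique reads in both).  Spearman rank correlation (ties
    by average ranks) runs over normalized expression of the intersection.
    """
    if len(samples) < 2:
        raise ValueError("cross_sample_summary needs at least two samples")
    names = list(samples)
    out: dict = {"samples": names, "pairs": {}}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = samples[names[i]], samples[names[j]]
            ka = a.set_index("key")
            kb = b.set_index("key")
            shared = ka.index.intersection(kb.index)
            gt5 = sum(
                1 for k in shared
                if ka.loc[k, "n_reads"] > 5 and kb.loc[k, "n_reads"] > 5
            )
            uniq2 = sum(
                1 for k in shared
                if ka.loc[k, "n_unique"] >= 2 and kb.loc[k, "n_unique"] >= 2
            )
            va = ka.loc[shared, "normalized"]
            vb = kb.loc[shared, "normalized"]
            if len(shared) >= 2 and va.nunique() > 1 and vb.nunique() > 1:
                rho = float(stats.spearmanr(va, vb).statistic)
            else:
                rho = float("nan")  # undefined on tiny or constant overlap
            out["pairs"][(names[i], names[j])] = {
                "n_shared": len(shared),
                "shared_gt5_reads": gt5,
                "shared_ge2_unique": uniq2,
                "spearman_rho": rho,
            }
    out["ecdf"] = {
        name: np.sort(df["normalized"].to_numpy()) for name, df in samples.items()
    }
    return out
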