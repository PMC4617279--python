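"""Candidate annotation against gene models.

Each candidate is intersected with the gene models to assign gene-structure
categories (a category is counted whenever either splice site overlaps the
feature type, so multi-membership is expected), a host gene, a predicted
exon-intron structure and a spliced length under the assumption that known
introns inside the circle are spliced out.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GeneModel, Transcript
from .junction_discovery import CircCandidate

log = logging.getLogger(__name__)

CATEGORIES = ("coding_exon", "utr5", "utr3", "intron", "lncRNA", "antisense", "intergenic")


@dataclass
class AnnotatedCirc:
    candidate: CircCandidate
    host_gene: Optional[str]
    categories: set
    exon_count: int
    spliced_length: int

    @property
    def key(self):
        return self.candidate.key


class FeatureIndex:
    """Interval trees over gene spans and exons, per contig."""

    def __init__(self, models: Sequence[GeneModel]):
        self.models = {g.gene_id: g for g in models}
        self.gene_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.exon_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for g in models:
            s, e = g.span
            self.gene_trees[g.contig][s:e] = g.gene_id
            for t in g.transcripts:
                for es, ee in t.exons:
                    self.exon_trees[g.contig][es:ee] = g.gene_id

    def genes_at(self, contig: str, point: int) -> set:
        return {iv.data for iv in self.gene_trees.get(contig, IntervalTree())[point]}

    def genes_over(self, contig: str, start: int, end: int) -> set:
        return {iv.data for iv in self.gene_trees.get(contig, IntervalTree())[start:end]}

    def exonic_genes_at(self, contig: str, point: int) -> set:
        return {iv.data for iv in self.exon_trees.get(contig, IntervalTree())[point]}


def _utr_category(gene: GeneModel, tx: Transcript, point: int) -> str:
    """Classify an exonic point of a coding transcript as utr5/utr3/coding.

    Without CDS records the coding_exon category subsumes the UTRs.
    """
    if not tx.cds:
        return "coding_exon"
    cds_lo = tx.cds[0][0]
    cds_hi = tx.cds[-1][1]
    if cds_lo <= point < cds_hi:
        return "coding_exon"
    before = point < cds_lo
    if gene.strand == "+":
        return "utr5" if before else "utr3"
    return "utr3" if before else "utr5"


def assign_categories(candidate: CircCandidate, index: FeatureIndex) -> set:
    """Category set from the candidate's two splice sites.

    For each splice site (first and last base of the circle span) every
    overlapped feature type adds its category: coding exons (split into
    UTRs when CDS records exist), introns of same-strand genes, lncRNA
    genes, antisense when only opposite-strand genes overlap, and
    intergenic when nothing overlaps at all.
    """
    sites = (candidate.start, candidate.end - 1)
    cats: set = set()
    any_overlap = False
    for point in sites:
        gids = index.genes_at(candidate.contig, point)
        if not gids:
            continue
        any_overlap = True
        same = [index.models[g] for g in gids if index.models[g].strand == candidate.strand]
        if not same:
            cats.add("antisense")
            continue
        for gene in same:
            exonic = False
            for t in gene.transcripts:
                for es, ee in t.exons:
                    if es <= point < ee:
                        exonic = True
                        if gene.biotype == "protein_coding":
                            cats.add(_utr_category(gene, t, point))
                        else:
                            cats.add("lncRNA")
                        break
            if not exonic:
                cats.add("intron")
    if not any_overlap:
        return {"intergenic"}
    return cats


def assign_host_gene(candidate: CircCandidate, index: FeatureIndex) -> Optional[str]:
    """Host = same-strand gene with the largest exonic overlap with the
    circle span; ties broken by smaller gene span, then gene_id."""
    gids = index.genes_over(candidate.contig, candidate.start, candidate.end)
    best: Optional[tuple] = None
    for gid in sorted(gids):
        gene = index.models[gid]
        if gene.strand != candidate.strand:
            continue
        overlap = 0
        for es, ee in gene.exon_union():
            overlap += max(0, min(ee, candidate.end) - max(es, candidate.start))
        gs, ge = gene.span
        rank = (-overlap, ge - gs, gid)
        if best is None or rank < best[0]:
            best = (rank, gid)
    if best is None or best[0][0] == 0:  # no exonic overlap at all
        return None
    return best[1]


def predict_structure(
    candidate: CircCandidate, index: FeatureIndex, host_gene: Optional[str]
) -> tuple[int, int]:
    """(exon_count, spliced_length) of the circle under its host transcript.

    The transcript whose annotated exon boundaries match the candidate's
    splice sites exactly is preferred; otherwise the transcript with the
    largest exonic overlap.  Spliced length sums that transcript's exonic
    bases inside the span (known introns spliced out); without any
    overlapping transcript the circle is taken as one unspliced exon.
    """
    start, end = candidate.start, candidate.end
    if host_gene is None:
        return 1, end - start
    gene = index.models[host_gene]
    chosen: Optional[Transcript] = None
    best_rank: Optional[tuple] = None
    for t in gene.transcripts:
        starts = {s for s, _ in t.exons}
        ends = {e for _, e in t.exons}
        exact = start in starts and end in ends
        overlap = sum(max(0, min(ee, end) - max(es, start)) for es, ee in t.exons)
        rank = (not exact, -overlap, t.transcript_id)
        if best_rank is None or rank < best_rank:
            best_rank, chosen = rank, t
    if chosen is None or best_rank[1] == 0:
        return 1, end - start
    exons_in = [(es, ee) for es, ee in chosen.exons if min(ee, end) > max(es, start)]
    spliced = sum(min(ee, end) - max(es, start) for es, ee in exons_in)
    return max(1, len(exons_in)), spliced


def annotate(
    candidates: Sequence[CircCandidate], models: Sequence[GeneModel]
) -> list[AnnotatedCirc]:
    """Full annotation pass; also fills the candidate objects in place so
    BED output carries categories, spliced length and host gene."""
    index = FeatureIndex(models)
    out = []
    for cand in candidates:
        cats = assign_categories(cand, index)
        host = assign_host_gene(cand, index)
        if cats == {"antisense"}:
            host = None  # antisense circles get no host (excluded downstream)
        n_ex, splen = predict_structure(cand, index, host)
        cand.categories = cats
        cand.spliced_length = splen
        cand.host_gene = host
        out.append(AnnotatedCirc(cand, host, cats, n_ex, splen))
    return out


def hotspot_table(annotated: Sequence[AnnotatedCirc], threshold: int = 10) -> pd.DataFrame:
    """Distinct circles per host gene; hotspot = strictly more than 10."""
    counts: dict[str, set] = defaultdict(set)
    for a in annotated:
        if a.host_gene is not None:
            counts[a.host_gene].add(a.key)
    rows = [
        {"gene_id": g, "n_circ": len(keys), "hotspot": len(keys) > threshold}
        for g, keys in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "n_circ", "hotspot"])


def category_counts(annotated: Sequence[AnnotatedCirc]) -> pd.DataFrame:
    """Candidates per category (multi-counting, so totals can exceed n)."""
    counter: dict[str, int] = {c: 0 for c in CATEGORIES}
    for a in annotated:
        for c in a.categories:
            counter[c] += 1
    return pd.DataFrame(
        [{"category": c, "n": counter[c]} for c in CATEGORIES],
        columns=["category", "n"],
    )
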