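"""Readers and writers for the standard formats the pipeline touches.

Coordinate convention: everything internal is 0-based half-open
(BED-compatible).  GTF's 1-based inclusive intervals are converted at the
boundary: ``[a, b]`` (1-based) becomes ``[a-1, b)``.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Optional

import gffutils
from Bio import SeqIO

from .config import biotype_bucket

log = logging.getLogger(__name__)

_ALPHABET = set("ACGTN")


class ParseError(ValueError):
    """Malformed input file (message names the offending record/line)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    """Contig name → uppercase nucleotide string (A/C/G/T/N only)."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ParseError(f"contig {name!r} has an empty sequence")
            bad = set(seq) - _ALPHABET
            if bad:
                raise ParseError(f"contig {name!r} contains non-ACGTN letters: {sorted(bad)}")

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __len__(self) -> int:
        return len(self.contigs)


@dataclass
class Transcript:
    """Exons as sorted, non-overlapping [start, end) genomic intervals."""

    transcript_id: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ParseError(f"transcript {self.transcript_id}: exon [{s},{e}) empty")
            if s < prev_end:
                raise ParseError(f"transcript {self.transcript_id}: overlapping exons")
            prev_end = e
        self.cds = sorted(self.cds)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Genomic [start, end) intervals between consecutive exons."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    biotype: str  # one of config.VALID_BIOTYPES
    strand: str   # '+' or '-'
    contig: str
    transcripts: list[Transcript]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ParseError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def span(self) -> tuple[int, int]:
        starts, ends = zip(*(t.span for t in self.transcripts))
        return min(starts), max(ends)

    def exon_union(self) -> list[tuple[int, int]]:
        """Merged union of all transcript exons (sorted, disjoint)."""
        ivs = sorted(iv for t in self.transcripts for iv in t.exons)
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [tuple(iv) for iv in merged]

    def union_length(self) -> int:
        return sum(e - s for s, e in self.exon_union())

    def junctions(self) -> list[tuple[int, int]]:
        """Annotated splice junctions as (donor_pos, acceptor_pos) tuples.

        Boundary coordinates are half-open exon edges; for a plus-strand
        intron [i0, i1) the donor boundary is i0 and the acceptor boundary
        i1, mirrored on the minus strand.
        """
        out: set[tuple[int, int]] = set()
        for t in self.transcripts:
            for i0, i1 in t.introns():
                if self.strand == "+":
                    out.add((i0, i1))
                else:
                    out.add((i1, i0))
        return sorted(out)


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    qualities: Optional[str] = None


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> Genome:
    """Load a FASTA file as a :class:`Genome`; soft-masking is uppercased."""
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in contigs:
            raise ParseError(f"{path}: duplicate FASTA header {rec.id!r}")
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise ParseError(f"{path}: no FASTA records found")
    return Genome(contigs)


def read_fastq(path: str) -> list[ReadRecord]:
    """Load FASTQ (Sanger Phred+33).  Qualities are kept but unused by
    detection, whose filters are purely alignment-based."""
    reads = []
    for rec in SeqIO.parse(path, "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(ReadRecord(rec.id, str(rec.seq).upper(), qual))
    return reads


def write_fasta(genome: Genome, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome.contigs:
            fh.write(f">{name}\n")
            seq = genome.contigs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[ReadRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qualities or "I" * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GTF (ENSEMBL dialect)
# ---------------------------------------------------------------------------

def read_gtf(path: str) -> list[GeneModel]:
    """Parse an ENSEMBL-dialect GTF into gene models.

    Requires ``gene_id`` and ``transcript_id`` on every exon row;
    ``gene_biotype`` is mapped through the dialect table in
    :mod:`circdetect.config`.  1-based inclusive coordinates become 0-based
    half-open.
    """
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, dict] = {}
    for kind in ("exon", "CDS"):
        for feat in db.features_of_type(kind):
            attrs = feat.attributes
            if "gene_id" not in attrs:
                raise ParseError(f"{path}: {kind} at {feat.seqid}:{feat.start} lacks gene_id")
            if "transcript_id" not in attrs:
                raise ParseError(
                    f"{path}: {kind} at {feat.seqid}:{feat.start} lacks transcript_id"
                )
            gid = attrs["gene_id"][0]
            tid = attrs["transcript_id"][0]
            entry = genes.setdefault(
                gid,
                {
                    "name": attrs.get("gene_name", [gid])[0],
                    "biotype": biotype_bucket(attrs.get("gene_biotype", ["other"])[0]),
                    "strand": feat.strand,
                    "contig": feat.seqid,
                    "tx": {},
                },
            )
            if feat.seqid != entry["contig"] or feat.strand != entry["strand"]:
                raise ParseError(f"{path}: gene {gid} spans contigs/strands")
            tx = entry["tx"].setdefault(tid, {"exon": [], "CDS": []})
            tx[kind].append((feat.start - 1, feat.end))  # 1-based closed → half-open

    models = []
    for gid, entry in genes.items():
        transcripts = [
            Transcript(tid, tx["exon"], tx["CDS"])
            for tid, tx in sorted(entry["tx"].items())
        ]
        models.append(
            GeneModel(gid, entry["name"], entry["biotype"], entry["strand"],
                      entry["contig"], transcripts)
        )
    models.sort(key=lambda g: (g.contig, g.span, g.gene_id))
    return models


def write_gtf(models: list[GeneModel], path: str, source: str = "circdetect") -> None:
    """Emit gene models back to ENSEMBL-dialect GTF (exon + CDS rows)."""
    with open(path, "w") as fh:
        for g in models:
            for t in g.transcripts:
                for kind, ivs in (("exon", t.exons), ("CDS", t.cds)):
                    for s, e in ivs:
                        attrs = (
                            f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                            f'gene_name "{g.gene_name}"; gene_biotype "{g.biotype}";'
                        )
                        fh.write(
                            f"{g.contig}\t{source}\t{kind}\t{s + 1}\t{e}\t.\t"
                            f"{g.strand}\t.\t{attrs}\n"
                        )


# ---------------------------------------------------------------------------
# BED6+4 candidate tables
# ---------------------------------------------------------------------------

BED_HEADER = (
    "#chrom\tstart\tend\tname\tscore\tstrand\tn_unique\tcategories\t"
    "spliced_length\thost_gene"
)


def write_bed(candidates, path: str, config_hash: str = "") -> None:
    """Write candidates as BED6+4.

    Columns: chrom, start, end, name, score (= total head-to-tail reads),
    strand, then unique-read count, comma-joined category list, spliced
    length and host gene id.  Unannotated fields are written as ``.``.
    """
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"#circdetect config={config_hash}\n")
        fh.write(BED_HEADER + "\n")
        for i, c in enumerate(candidates, 1):
            cats = ",".join(sorted(c.categories)) if getattr(c, "categories", None) else "."
            splen = getattr(c, "spliced_length", None)
            host = getattr(c, "host_gene", None)
            fh.write(
                f"{c.contig}\t{c.start}\t{c.end}\tcirc_{i}\t{c.n_reads}\t{c.strand}\t"
                f"{c.n_unique}\t{cats}\t{splen if splen is not None else '.'}\t"
                f"{host if host is not None else '.'}\n"
            )


@dataclass
class BedCandidate:
    """Round-trippable view of one BED6+4 row."""

    contig: str
    start: int
    end: int
    name: str
    n_reads: int
    strand: str
    n_unique: int
    categories: Optional[set] = None
    spliced_length: Optional[int] = None
    host_gene: Optional[str] = None


def read_bed(path: str) -> list[BedCandidate]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 10:
                raise ParseError(f"{path}: expected 10 BED6+4 columns, got {len(f)}")
            out.append(
                BedCandidate(
                    contig=f[0], start=int(f[1]), end=int(f[2]), name=f[3],
                    n_reads=int(f[4]), strand=f[5], n_unique=int(f[6]),
                    categories=set(f[7].split(",")) if f[7] != "." else None,
                    spliced_length=int(f[8]) if f[8] != "." else None,
                    host_gene=f[9] if f[9] != "." else None,
                )
            )
    return out
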