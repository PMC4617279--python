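"""Simulated RNA-seq with planted linear and back-splice junctions.

The generator emulates the statistical structure the analysis assumes:
a multi-gene toy genome whose introns carry GT/AG signals on the gene
strand, single-end ~100-nt reads drawn uniformly from spliced linear
transcripts, reads wrapping the head-to-tail junction of planted circles
at controlled circular-to-linear ratios (a high "blood-like" against a low
"liver-like" profile), rRNA contamination at a set fraction from decoy
contigs, and a uniform substitution error rate.  Every read's origin and
every planted junction's spanning-read count are recorded in a ground
truth manifest used as the acceptance oracle.

Read allocation is a single multinomial over {rRNA, per-gene linear
templates, per-circle junction windows}; circle weights are chosen so the
expected ratio of circular-junction reads to per-junction linear reads
equals each circle's drawn ratio, which keeps totals exactly at ``depth``
and makes ratios converge to the configured distribution as depth grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .alignment_core import revcomp
from .io_formats import Genome, GeneModel, ReadRecord, Transcript

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclass
class SimConfig:
    """Study conditions for one simulated sample.

    ``circ_ratio_mean``/``circ_ratio_sigma`` parameterise the lognormal
    distribution of per-circle circular-to-linear read ratios; the
    blood-like profile has mean well above 1, the liver-like profile well
    below 1, mirroring the contrast between a circRNA-rich and a
    circRNA-poor tissue.
    """

    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (4, 6)
    exon_len: tuple[int, int] = (90, 220)
    intron_len: tuple[int, int] = (150, 400)
    intergenic: tuple[int, int] = (200, 400)
    read_len: int = 100
    anchor_length: int = 20
    circ_genes: float = 0.5
    circ_ratio_mean: float = 4.0
    circ_ratio_sigma: float = 0.5
    circ_exon_range: tuple[int, int] = (1, 3)
    rrna_fraction: float = 0.05
    n_rrna: int = 3
    rrna_len: int = 1500
    lnc_fraction: float = 0.1
    error_rate: float = 0.0
    depth: int = 50_000
    min_circ_spanning: int = 2
    expression_sigma: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        for frac in (self.circ_genes, self.rrna_fraction, self.lnc_fraction):
            if not 0.0 <= frac <= 1.0:
                raise SimConfigError("fractions must lie in [0, 1]")
        if self.read_len < 2 * self.anchor_length:
            raise SimConfigError("read_len must be at least 2 × anchor_length")
        if self.intron_len[0] < 4:
            raise SimConfigError("introns need at least 4 nt for the GT..AG signal")
        if self.exons_per_gene[0] < 2:
            raise SimConfigError("genes need at least 2 exons to carry a junction")
        if self.error_rate < 0 or self.error_rate >= 1:
            raise SimConfigError("error_rate must lie in [0, 1)")

    @classmethod
    def blood_like(cls, **kw) -> "SimConfig":
        """High circular-to-linear profile (mean ratio ≫ 1)."""
        return cls(circ_ratio_mean=4.0, **kw)

    @classmethod
    def liver_like(cls, **kw) -> "SimConfig":
        """Low circular-to-linear profile (mean ratio ≪ 1)."""
        return cls(circ_ratio_mean=0.1, **kw)


@dataclass
class PlantedCircle:
    gene_id: str
    contig: str
    strand: str
    tx_exon_indices: tuple[int, ...]  # transcript-order exon indices in the circle
    donor_pos: int
    acceptor_pos: int
    ratio: float

    @property
    def key(self) -> tuple:
        return (self.contig, self.strand, self.donor_pos, self.acceptor_pos)


@dataclass
class TruthJunction:
    contig: str
    strand: str
    donor_pos: int
    acceptor_pos: int
    type: str  # 'linear' | 'circular'
    gene_id: str
    planted_read_count: int = 0
    planted_ratio: float = float("nan")

    @property
    def key(self) -> tuple:
        return (self.contig, self.strand, self.donor_pos, self.acceptor_pos)


@dataclass
class ReadOrigin:
    kind: str  # 'linear' | 'circle' | 'rrna'
    gene_id: str = ""
    spans: list = field(default_factory=list)  # junction keys with full anchors


@dataclass
class SimTruth:
    junctions: list[TruthJunction]
    reads: dict[str, ReadOrigin]

    def circular(self) -> list[TruthJunction]:
        return [j for j in self.junctions if j.type == "circular"]

    def linear(self) -> list[TruthJunction]:
        return [j for j in self.junctions if j.type == "linear"]

    def counts(self, jtype: Optional[str] = None) -> dict[tuple, int]:
        return {
            j.key: j.planted_read_count
            for j in self.junctions
            if jtype is None or j.type == jtype
        }


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _intron_seq(rng: np.random.Generator, n: int, strand: str) -> str:
    """Random intron carrying the splice signal on the gene strand: a plus
    intron starts GT and ends AG; on the genomic plus strand a minus-gene
    intron therefore reads CT ... AC."""
    core = _rand_seq(rng, n - 4)
    return ("GT" + core + "AG") if strand == "+" else ("CT" + core + "AC")


def build_genome(cfg: SimConfig) -> tuple[Genome, list[GeneModel]]:
    """Construct the toy genome and its gene models.

    One contig carries all genes separated by intergenic spacers of at
    least ``read_len``; genes alternate pseudo-randomly between strands and
    a configured fraction are long non-coding.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 11])
    parts: list[str] = []
    pos = 0
    models: list[GeneModel] = []
    for gi in range(cfg.n_genes):
        spacer = int(rng.integers(*cfg.intergenic))
        parts.append(_rand_seq(rng, spacer))
        pos += spacer
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "lncRNA" if rng.random() < cfg.lnc_fraction else "protein_coding"
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        exons: list[tuple[int, int]] = []
        for ei in range(n_ex):
            if ei > 0:
                ilen = int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))
                parts.append(_intron_seq(rng, ilen, strand))
                pos += ilen
            elen = int(rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1))
            parts.append(_rand_seq(rng, elen))
            exons.append((pos, pos + elen))
            pos += elen
        gid = f"g{gi + 1:03d}"
        models.append(
            GeneModel(gid, gid.upper(), biotype, strand, "chr1",
                      [Transcript(f"t{gi + 1:03d}", exons)])
        )
    tail = int(rng.integers(*cfg.intergenic))
    parts.append(_rand_seq(rng, tail))
    seq = bytearray("".join(parts).encode())
    _scrub_decoy_signals(seq, models, cfg)
    genome = Genome({"chr1": seq.decode()})
    return genome, models


def _scrub_decoy_signals(seq: bytearray, models: list[GeneModel], cfg: SimConfig) -> None:
    """Remove shifted GT/AG (or CT/AC) pairs around every junction pair.

    A breakpoint is ambiguous when, for some shift δ, a second splice-signal
    pair flanks the junction boundaries at (donor+δ, acceptor+δ).  Such
    decoy contexts would make a planted junction undetectable by
    construction (the unambiguous-breakpoint filter rejects every read), so
    the generator edits one base of each decoy signal.  All (intron-start,
    intron-end) combinations of a gene are scrubbed, which covers linear
    junctions and any back-splice the circle planner may later choose.
    Real data keeps such contexts; the pipeline handles them by rejection.
    """
    delta_max = cfg.read_len - 2 * cfg.anchor_length + 4
    for gene in models:
        introns = sorted(
            {iv for t in gene.transcripts for iv in t.introns()}
        )
        starts = [i0 for i0, _ in introns]
        ends = [i1 for _, i1 in introns]
        for p in starts:
            for q in ends:
                changed = True
                while changed:
                    changed = False
                    for delta in range(-delta_max, delta_max + 1):
                        if delta == 0:
                            continue
                        pp, qq = p + delta, q + delta
                        if pp < 0 or qq - 2 < 0 or pp + 2 > len(seq) or qq > len(seq):
                            continue
                        donor2 = seq[pp : pp + 2]
                        acc2 = seq[qq - 2 : qq]
                        if (donor2 == b"GT" and acc2 == b"AG") or (
                            donor2 == b"CT" and acc2 == b"AC"
                        ):
                            seq[pp + 1] = ord("A")  # break the decoy donor signal
                            changed = True


def build_rrna(cfg: SimConfig) -> Genome:
    """Random rRNA decoy contigs (the pipeline's second reference)."""
    rng = np.random.default_rng([cfg.seed, 12])
    return Genome({f"rRNA_{i + 1}": _rand_seq(rng, cfg.rrna_len) for i in range(cfg.n_rrna)})


# ---------------------------------------------------------------------------
# transcript / circle sequences
# ---------------------------------------------------------------------------

def transcript_sequence(genome: Genome, gene: GeneModel, tx: Transcript) -> str:
    chunks = [genome[gene.contig][s:e] for s, e in tx.exons]
    if gene.strand == "-":
        return revcomp("".join(chunks))
    return "".join(chunks)


def _tx_order_exons(gene: GeneModel, tx: Transcript) -> list[tuple[int, int]]:
    return tx.exons if gene.strand == "+" else list(reversed(tx.exons))


def circle_sequence(genome: Genome, gene: GeneModel, circ: PlantedCircle) -> str:
    tx = gene.transcripts[0]
    ordered = _tx_order_exons(gene, tx)
    chunks = []
    for i in circ.tx_exon_indices:
        s, e = ordered[i]
        seq = genome[gene.contig][s:e]
        chunks.append(revcomp(seq) if gene.strand == "-" else seq)
    return "".join(chunks)


def choose_circles(models: list[GeneModel], cfg: SimConfig) -> list[PlantedCircle]:
    """Plant one circle per selected gene on internal exons only, so both
    flanking introns provide the GT/AG back-splice signals."""
    rng = np.random.default_rng([cfg.seed, 13])
    n_target = round(cfg.circ_genes * len(models))
    order = rng.permutation(len(models))
    circles: list[PlantedCircle] = []
    for gi in order:
        if len(circles) >= n_target:
            break
        gene = models[gi]
        tx = gene.transcripts[0]
        ordered = _tx_order_exons(gene, tx)
        n = len(ordered)
        if n < 3:
            continue
        runs = []
        for start in range(1, n - 1):
            for length in range(cfg.circ_exon_range[0], cfg.circ_exon_range[1] + 1):
                stop = start + length
                if stop > n - 1:
                    break
                total = sum(e - s for s, e in ordered[start:stop])
                if total >= cfg.read_len:
                    runs.append((start, stop))
        if not runs:
            continue
        start, stop = runs[int(rng.integers(len(runs)))]
        first_s, first_e = ordered[start]
        last_s, last_e = ordered[stop - 1]
        if gene.strand == "+":
            acceptor, donor = first_s, last_e
        else:
            acceptor, donor = first_e, last_s
        ratio = float(rng.lognormal(
            math.log(cfg.circ_ratio_mean) - cfg.circ_ratio_sigma**2 / 2,
            cfg.circ_ratio_sigma,
        ))
        circles.append(
            PlantedCircle(gene.gene_id, gene.contig, gene.strand,
                          tuple(range(start, stop)), donor, acceptor, ratio)
        )
    return circles


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _apply_errors(seqs: list[str], rng: np.random.Generator, rate: float) -> list[str]:
    if rate <= 0 or not seqs:
        return seqs
    out = list(seqs)
    n_err = rng.binomial([len(s) for s in out], rate)
    for i in np.nonzero(n_err)[0]:
        s = list(out[i])
        pos = rng.choice(len(s), size=n_err[i], replace=False)
        for p in pos:
            choices = [b for b in "ACGT" if b != s[p]]
            s[p] = choices[int(rng.integers(3))]
        out[i] = "".join(s)
    return out


def simulate_reads(
    genome: Genome,
    models: list[GeneModel],
    cfg: SimConfig,
    rrna: Optional[Genome] = None,
) -> tuple[list[ReadRecord], SimTruth]:
    """Draw ``cfg.depth`` reads and the matching ground-truth manifest.

    Linear reads start uniformly over the spliced transcript; circle reads
    are drawn from the window that leaves at least ``anchor_length`` bases
    on each side of the head-to-tail junction (and stays within the
    circle's terminal exons, so the rest of the read maps contiguously on
    the genome side it extends into).  Reads are emitted on either strand
    with probability ½ (unstranded library).
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 14])
    if cfg.depth == 0:
        return [], SimTruth([], {})
    A, rl = cfg.anchor_length, cfg.read_len
    circles = choose_circles(models, cfg)

    # templates
    tx_seqs: dict[str, str] = {}
    junction_coords: dict[str, list[tuple[int, tuple]]] = {}  # gene → (tx coord, key)
    truth_junctions: dict[tuple, TruthJunction] = {}
    usable_genes: list[GeneModel] = []
    for gene in models:
        tx = gene.transcripts[0]
        seq = transcript_sequence(genome, gene, tx)
        if len(seq) < rl:
            continue
        usable_genes.append(gene)
        tx_seqs[gene.gene_id] = seq
        ordered = _tx_order_exons(gene, tx)
        coords = []
        cum = 0
        for i in range(len(ordered) - 1):
            cum += ordered[i][1] - ordered[i][0]
            s_next, e_next = ordered[i + 1]
            if gene.strand == "+":
                donor, acceptor = ordered[i][1], s_next
            else:
                donor, acceptor = ordered[i][0], e_next
            key = (gene.contig, gene.strand, donor, acceptor)
            coords.append((cum, key))
            truth_junctions[key] = TruthJunction(*key, "linear", gene.gene_id)
        junction_coords[gene.gene_id] = coords
    if not usable_genes:
        raise SimConfigError("no transcript is at least read_len long")
    circles = [c for c in circles if c.gene_id in tx_seqs]
    for c in circles:
        truth_junctions[c.key] = TruthJunction(
            *c.key, "circular", c.gene_id, planted_ratio=c.ratio
        )

    # allocation weights
    w = rng.lognormal(0.0, cfg.expression_sigma, len(usable_genes))
    u = w / w.sum()
    span_win = rl - 2 * A + 1
    cat_probs: list[float] = []
    cat_kind: list[tuple] = []
    for gene, ug in zip(usable_genes, u):
        cat_probs.append(ug)
        cat_kind.append(("linear", gene.gene_id))
    for c in circles:
        gi = next(i for i, g in enumerate(usable_genes) if g.gene_id == c.gene_id)
        tlen = len(tx_seqs[c.gene_id])
        s_g = span_win / (tlen - rl + 1)
        cat_probs.append(c.ratio * u[gi] * s_g)
        cat_kind.append(("circle", c.gene_id))
    probs = np.asarray(cat_probs)
    probs = probs / probs.sum() * (1.0 - cfg.rrna_fraction)
    probs = np.concatenate(([cfg.rrna_fraction], probs))
    counts = rng.multinomial(cfg.depth, probs)

    # enforce a minimum spanning count per circle by moving reads from the
    # host gene's linear pool (depth preserved)
    lin_index = {kind[1]: 1 + i for i, kind in enumerate(cat_kind) if kind[0] == "linear"}
    for i, kind in enumerate(cat_kind):
        if kind[0] != "circle":
            continue
        short = cfg.min_circ_spanning - counts[1 + i]
        if short > 0:
            j = lin_index[kind[1]]
            move = min(short, counts[j])
            counts[j] -= move
            counts[1 + i] += move

    reads: list[ReadRecord] = []
    origins: dict[str, ReadOrigin] = {}
    seqs: list[str] = []
    metas: list[ReadOrigin] = []

    # rRNA reads
    n_rrna_reads = int(counts[0])
    if n_rrna_reads and rrna is not None:
        names = list(rrna.contigs)
        picks = rng.integers(0, len(names), n_rrna_reads)
        for pi in picks:
            contig = names[int(pi)]
            seq = rrna[contig]
            start = int(rng.integers(0, len(seq) - rl + 1))
            frag = seq[start : start + rl]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            seqs.append(frag)
            metas.append(ReadOrigin("rrna"))
    elif n_rrna_reads:
        raise SimConfigError("rrna_fraction > 0 but no rRNA decoy genome supplied")

    # linear transcript reads
    for gene, cnt in zip(usable_genes, counts[1 : 1 + len(usable_genes)]):
        tseq = tx_seqs[gene.gene_id]
        starts = rng.integers(0, len(tseq) - rl + 1, int(cnt))
        jc = junction_coords[gene.gene_id]
        for s in starts:
            s = int(s)
            frag = tseq[s : s + rl]
            spans = [key for coord, key in jc if s + A <= coord <= s + rl - A]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            seqs.append(frag)
            metas.append(ReadOrigin("linear", gene.gene_id, spans))
            for key in spans:
                truth_junctions[key].planted_read_count += 1

    # circle junction reads
    for c, cnt in zip(circles, counts[1 + len(usable_genes) :]):
        cseq = circle_sequence(genome, next(g for g in usable_genes if g.gene_id == c.gene_id), c)
        clen = len(cseq)
        gene = next(g for g in usable_genes if g.gene_id == c.gene_id)
        ordered = _tx_order_exons(gene, gene.transcripts[0])
        len_first = ordered[c.tx_exon_indices[0]][1] - ordered[c.tx_exon_indices[0]][0]
        len_last = ordered[c.tx_exon_indices[-1]][1] - ordered[c.tx_exon_indices[-1]][0]
        lo = max(A, rl - len_first)
        hi = min(rl - A, len_last)
        if lo > hi:
            raise SimConfigError(
                f"circle on {c.gene_id}: terminal exons too short for a "
                f"{rl}-nt read with {A}-nt anchors on each side"
            )
        overhangs = rng.integers(lo, hi + 1, int(cnt))
        for ell in overhangs:
            ell = int(ell)
            frag = cseq[clen - ell :] + cseq[: rl - ell]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            seqs.append(frag)
            metas.append(ReadOrigin("circle", c.gene_id, [c.key]))
            truth_junctions[c.key].planted_read_count += 1

    seqs = _apply_errors(seqs, rng, cfg.error_rate)
    width = len(str(len(seqs)))
    for i, (seq, meta) in enumerate(zip(seqs, metas), 1):
        rid = f"read_{i:0{width}d}"
        reads.append(ReadRecord(rid, seq, "I" * len(seq)))
        origins[rid] = meta

    junctions = sorted(
        truth_junctions.values(),
        key=lambda j: (j.contig, j.donor_pos, j.acceptor_pos, j.strand),
    )
    return reads, SimTruth(junctions, origins)


# ---------------------------------------------------------------------------
# manifest I/O and evaluation
# ---------------------------------------------------------------------------

def truth_to_frame(truth: SimTruth) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": j.contig, "strand": j.strand, "donor_pos": j.donor_pos,
                "acceptor_pos": j.acceptor_pos, "type": j.type, "gene_id": j.gene_id,
                "planted_read_count": j.planted_read_count,
                "planted_ratio": j.planted_ratio,
            }
            for j in truth.junctions
        ]
    )


def write_truth(truth: SimTruth, path: str) -> None:
    truth_to_frame(truth).to_csv(path, sep="\t", index=False)


def evaluate_detection(candidates, truth: SimTruth, min_planted: int = 2) -> dict:
    """Sensitivity / false-junction counts of detected circles vs truth.

    Sensitivity is computed over planted circles with at least
    ``min_planted`` spanning reads; any detected circular junction absent
    from the full planted set counts as false.
    """
    planted_all = {j.key for j in truth.circular()}
    planted_eval = {
        j.key for j in truth.circular() if j.planted_read_count >= min_planted
    }
    detected = {c.key for c in candidates}
    tp = detected & planted_eval
    false = detected - planted_all
    sensitivity = len(tp) / len(planted_eval) if planted_eval else float("nan")
    return {
        "n_planted": len(planted_eval),
        "n_detected": len(detected),
        "n_true_positive": len(tp),
        "n_false": len(false),
        "sensitivity": sensitivity,
        "false_junctions": sorted(false),
    }
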