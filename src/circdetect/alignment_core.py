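"""Ungapped end-to-end alignment against small references.

The detection method needs three alignment services:

* an rRNA screen and a contiguous-mapping screen over full-length reads
  (a read is removed if it has *any* end-to-end placement within a small
  mismatch budget) — served by exact k-mer seeding with pigeonhole
  guarantees plus direct verification;
* exhaustive scoring of 20-nt anchors over every placement on both strands,
  so that best and second-best alignment scores are exact — served by a
  2-bit-packed XOR/popcount scan (a query of ≤32 nt fits one 64-bit word
  per placement).

Scoring model: ``score = 2·matches − 6·mismatches`` over the full query.
A perfect 20-mer scores 40; each mismatch costs 8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .config import DetectionConfig
from .io_formats import Genome, ReadRecord

log = logging.getLogger(__name__)

NEG_INF = -(10**9)  # stand-in for "no second-best alignment"

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
_CODE[ord("a")] = 0
_CODE[ord("c")] = 1
_CODE[ord("g")] = 2
_CODE[ord("t")] = 3


def encode(seq: str) -> np.ndarray:
    """Nucleotides → uint8 codes (A=0,C=1,G=2,T=3, anything else 4)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def encode_query(seq: str) -> np.ndarray:
    """Like :func:`encode` but N becomes 5 so it never matches genomic N."""
    codes = encode(seq).copy()
    codes[codes == 4] = 5
    return codes


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = np.where(codes < 4, 3 - codes, codes)
    return out[::-1].copy()


@dataclass(frozen=True)
class Alignment:
    """One ungapped end-to-end placement of a query."""

    query_id: str
    contig: str
    start: int
    end: int
    strand: str
    mismatches: int
    score: int

    def __post_init__(self):
        assert self.end - self.start >= 1


@dataclass
class AnchorHit:
    """Best placement of one read anchor plus the runner-up score.

    ``second_best_score`` is taken over *all* placements on both strands of
    every contig (not only those within the hit-listing mismatch budget), so
    the score-gap filter compares against the true runner-up.
    """

    anchor_side: str  # 'head' or 'tail'
    best: Alignment
    second_best_score: int = NEG_INF

    @property
    def score_gap(self) -> int:
        return self.best.score - self.second_best_score


# ---------------------------------------------------------------------------
# index
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Exact k-mer positions plus packed windows for exhaustive scans.

    ``k`` defaults to 12; k-mers containing N are not indexed.  Packed
    window arrays (one uint64 per placement, 2 bits per base) are built
    lazily per query length and cached.
    """

    def __init__(self, genome: Genome, k: int = 12):
        if k < 1 or k > 31:
            raise ValueError("seed length k must be in [1, 31]")
        self.k = k
        self.contig_names: list[str] = list(genome.contigs)
        self.codes: dict[str, np.ndarray] = {
            name: encode(seq) for name, seq in genome.contigs.items()
        }
        self._kmer_pos: dict[str, dict[int, np.ndarray]] = {}
        self._packed: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}
        for name, codes in self.codes.items():
            self._kmer_pos[name] = self._build_kmers(codes, k)

    @staticmethod
    def _build_kmers(codes: np.ndarray, k: int) -> dict[int, np.ndarray]:
        n = len(codes) - k + 1
        if n <= 0:
            return {}
        win = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = ~(win == 4).any(axis=1)
        powers = (4 ** np.arange(k, dtype=np.int64))[::-1]
        keys = win.astype(np.int64) @ powers
        keys = keys[valid]
        pos = np.nonzero(valid)[0]
        order = np.argsort(keys, kind="stable")
        keys, pos = keys[order], pos[order]
        bounds = np.nonzero(np.diff(keys))[0] + 1
        starts = np.concatenate(([0], bounds))
        ends = np.concatenate((bounds, [len(keys)]))
        return {int(keys[s]): pos[s:e].copy() for s, e in zip(starts, ends)}

    def kmer_positions(self, contig: str, kmer_codes: np.ndarray) -> np.ndarray:
        """Exact positions of a k-mer (given as codes) on a contig's + strand."""
        if (kmer_codes >= 4).any():
            return np.empty(0, dtype=np.int64)
        powers = (4 ** np.arange(self.k, dtype=np.int64))[::-1]
        key = int(kmer_codes.astype(np.int64) @ powers)
        return self._kmer_pos[contig].get(key, np.empty(0, dtype=np.int64))

    def packed_windows(self, contig: str, m: int) -> tuple[np.ndarray, np.ndarray]:
        """(packed, n_mask): packed[p] holds bases p..p+m−1 in 2 bits each;
        n_mask[p] is True where the window contains an N."""
        key = (contig, m)
        if key not in self._packed:
            codes = self.codes[contig]
            n = len(codes) - m + 1
            if n <= 0:
                packed = np.empty(0, dtype=np.uint64)
                nmask = np.empty(0, dtype=bool)
            else:
                packed = np.zeros(n, dtype=np.uint64)
                isn = codes == 4
                nmask = np.zeros(n, dtype=bool)
                safe = np.where(isn, 0, codes).astype(np.uint64)
                for j in range(m):
                    packed |= safe[j : j + n] << np.uint64(2 * j)
                    nmask |= isn[j : j + n]
            self._packed[key] = (packed, nmask)
        return self._packed[key]


def build_index(genome: Genome, k: int = 12) -> GenomeIndex:
    """Build the combined k-mer / packed-window index for a genome."""
    return GenomeIndex(genome, k)


def _pack_query(codes: np.ndarray) -> int:
    val = 0
    for j, c in enumerate(codes):
        val |= int(c & 3) << (2 * j)
    return val


def _mismatch_counts(index: GenomeIndex, contig: str, q_codes: np.ndarray) -> np.ndarray:
    """Mismatch count of the query at every placement on a contig (+ frame).

    Placements whose window contains N, or where the query contains N,
    count those bases as mismatches exactly (computed via a correction
    pass), so results equal the naive definition.
    """
    m = len(q_codes)
    packed, nmask = index.packed_windows(contig, m)
    n = len(packed)
    if n == 0:
        return np.empty(0, dtype=np.int32)
    mask01 = np.uint64(int("01" * m, 2))  # low bit of each 2-bit base pair
    q_has_n = bool((q_codes >= 4).any())
    qpack = np.uint64(_pack_query(np.where(q_codes >= 4, 0, q_codes)))
    diff = packed ^ qpack
    z = (diff | (diff >> np.uint64(1))) & mask01
    cnt = np.bitwise_count(z).astype(np.int32)
    if q_has_n or nmask.any():
        # slow correction only where Ns are involved
        idx = np.nonzero(nmask)[0] if not q_has_n else np.arange(n)
        codes = index.codes[contig]
        for p in idx:
            wind = codes[p : p + m]
            cnt[p] = int(np.count_nonzero((wind != q_codes) | (wind == 4) | (q_codes >= 4)))
    return cnt


# ---------------------------------------------------------------------------
# exhaustive query alignment (anchors)
# ---------------------------------------------------------------------------

@dataclass
class QueryScan:
    """Full scan result for one query: hits within the mismatch budget plus
    the two best scores over all placements/strands/contigs."""

    hits: list[Alignment]
    best_score: int
    second_best_score: int


def scan_query(
    query: str,
    index: GenomeIndex,
    max_mismatches: int,
    cfg: DetectionConfig,
    query_id: str = "q",
) -> QueryScan:
    """Exhaustively score a (≤32 nt) query at every placement, both strands."""
    m = len(query)
    if m > 32:
        raise ValueError("scan_query handles queries of at most 32 nt")
    fwd = encode_query(query)
    rev = revcomp_codes(fwd)
    hits: list[Alignment] = []
    all_best = NEG_INF
    all_second = NEG_INF
    for contig in index.contig_names:
        for strand, codes in (("+", fwd), ("-", rev)):
            cnt = _mismatch_counts(index, contig, codes)
            if len(cnt) == 0:
                continue
            for p in np.nonzero(cnt <= max_mismatches)[0]:
                mm = int(cnt[p])
                hits.append(
                    Alignment(query_id, contig, int(p), int(p) + m, strand, mm,
                              cfg.score(m, mm))
                )
            # track top-two scores over *all* placements
            if len(cnt) == 1:
                top2 = [int(cnt[0])]
            else:
                part = np.partition(cnt, 1)[:2]
                top2 = [int(part[0]), int(part[1])]
            for mm in top2:
                s = cfg.score(m, mm)
                if s > all_best:
                    all_best, all_second = s, all_best
                elif s > all_second:
                    all_second = s
    hits.sort(key=lambda a: (-a.score, a.contig, a.start, a.strand))
    return QueryScan(hits, all_best, all_second)


def align_ungapped(
    query: str,
    index: GenomeIndex,
    max_mismatches: int,
    cfg: Optional[DetectionConfig] = None,
    query_id: str = "q",
) -> list[Alignment]:
    """All end-to-end placements of ``query`` with ≤ ``max_mismatches``.

    Sorted by score descending, ties broken by (contig, start, strand).
    Queries of ≤32 nt use the exhaustive packed scan; longer queries use
    pigeonhole seeding (requires ``(max_mismatches+1)·k ≤ len(query)``).
    """
    cfg = cfg or DetectionConfig()
    if len(query) <= 32:
        return scan_query(query, index, max_mismatches, cfg, query_id).hits
    hits = []
    for contig, start, strand, mm in _seeded_placements(query, index, max_mismatches):
        hits.append(
            Alignment(query_id, contig, start, start + len(query), strand, mm,
                      cfg.score(len(query), mm))
        )
    hits.sort(key=lambda a: (-a.score, a.contig, a.start, a.strand))
    return hits


def _seeded_placements(
    query: str, index: GenomeIndex, max_mm: int
) -> list[tuple[str, int, str, int]]:
    """Seed-and-verify placements of a long query (both strands).

    Pigeonhole: with ``max_mm+1`` disjoint exact seeds of length k, any
    placement with ≤ max_mm mismatches leaves at least one seed intact.
    """
    k = index.k
    m = len(query)
    n_seeds = max_mm + 1
    if n_seeds * k > m:
        raise ValueError(
            f"query of {m} nt too short for {n_seeds} disjoint {k}-mers"
        )
    fwd = encode_query(query)
    rev = revcomp_codes(fwd)
    offsets = [i * k for i in range(n_seeds)]
    out = []
    for strand, codes in (("+", fwd), ("-", rev)):
        for contig in index.contig_names:
            gcodes = index.codes[contig]
            cand: set[int] = set()
            for off in offsets:
                seed = codes[off : off + k]
                for p in index.kmer_positions(contig, seed):
                    s = int(p) - off
                    if 0 <= s <= len(gcodes) - m:
                        cand.add(s)
            for s in sorted(cand):
                wind = gcodes[s : s + m]
                mm = int(np.count_nonzero((wind != codes) | (wind == 4)))
                if mm <= max_mm:
                    out.append((contig, s, strand, mm))
    return out


def best_end_to_end(
    read: ReadRecord, index: GenomeIndex, max_mm: int
) -> Optional[Alignment]:
    """Best (fewest-mismatch) end-to-end placement of a full read, or None."""
    cfg = DetectionConfig()
    try:
        placements = _seeded_placements(read.sequence, index, max_mm)
    except ValueError:
        # read too short for seeding; fall back to exhaustive if it fits
        if len(read.sequence) <= 32:
            hits = scan_query(read.sequence, index, max_mm, cfg, read.read_id).hits
            return hits[0] if hits else None
        raise
    if not placements:
        return None
    contig, start, strand, mm = min(
        placements, key=lambda t: (t[3], t[0], t[1], t[2])
    )
    return Alignment(read.read_id, contig, start, start + len(read.sequence),
                     strand, mm, cfg.score(len(read.sequence), mm))


# ---------------------------------------------------------------------------
# read screens
# ---------------------------------------------------------------------------

def fraction_rrna(
    reads: Sequence[ReadRecord],
    rrna_index: Optional[GenomeIndex],
    max_mm: int = 2,
) -> tuple[list[ReadRecord], float]:
    """Remove reads with any end-to-end rRNA placement within ``max_mm``.

    Returns (kept reads, removed fraction).  With no rRNA reference every
    read is kept and the fraction is 0.
    """
    if rrna_index is None or not reads:
        return list(reads), 0.0
    kept = [r for r in reads if best_end_to_end(r, rrna_index, max_mm) is None]
    return kept, (len(reads) - len(kept)) / len(reads)


def drop_contiguous(
    reads: Sequence[ReadRecord],
    genome_index: GenomeIndex,
    max_mm: int = 2,
) -> tuple[list[ReadRecord], list[Alignment]]:
    """Split reads into (unmapped, contiguous alignments).

    Reads that align end-to-end to the genome within ``max_mm`` mismatches
    are excluded from junction discovery; their best alignments are kept
    because the quantification stage counts them over gene exons.
    """
    unmapped: list[ReadRecord] = []
    mapped: list[Alignment] = []
    for r in reads:
        aln = best_end_to_end(r, genome_index, max_mm)
        if aln is None:
            unmapped.append(r)
        else:
            mapped.append(aln)
    return unmapped, mapped


# ---------------------------------------------------------------------------
# SAM interchange (optional external-aligner path)
# ---------------------------------------------------------------------------

def alignments_to_sam(
    alignments: Iterable[Alignment], genome: Genome, path: str
) -> None:
    """Write ungapped alignments as SAM (for inspection or interchange)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": len(genome.contigs[n])} for n in genome.contigs],
    }
    names = list(genome.contigs)
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for a in alignments:
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = a.query_id
            rec.reference_id = names.index(a.contig)
            rec.reference_start = a.start
            rec.flag = 16 if a.strand == "-" else 0
            rec.mapping_quality = 255
            rec.cigarstring = f"{a.end - a.start}M"
            rec.set_tag("NM", a.mismatches)
            rec.set_tag("AS", a.score)
            fh.write(rec)


def alignments_from_sam(path: str, cfg: Optional[DetectionConfig] = None) -> list[Alignment]:
    """Ingest ungapped records from a SAM/BAM file.

    Records with indels/clipping in the CIGAR, or unmapped records, are
    skipped with a warning — the detection contract is strictly ungapped
    end-to-end.  Mismatch counts come from NM tags (0 if absent); scores
    are recomputed under the internal model so downstream filters behave
    identically to the internal aligner.
    """
    import pysam

    cfg = cfg or DetectionConfig()
    out: list[Alignment] = []
    skipped = 0
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                skipped += 1
                continue
            cig = rec.cigartuples or []
            if len(cig) != 1 or cig[0][0] != 0:  # anything but a single M run
                skipped += 1
                continue
            length = cig[0][1]
            mm = int(rec.get_tag("NM")) if rec.has_tag("NM") else 0
            out.append(
                Alignment(
                    rec.query_name,
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_start + length,
                    "-" if rec.is_reverse else "+",
                    mm,
                    cfg.score(length, mm),
                )
            )
    if skipped:
        log.warning("alignments_from_sam: skipped %d non-ungapped/unmapped records", skipped)
    return out
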