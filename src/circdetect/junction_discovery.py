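"""Back-splice junction discovery from unmapped reads.

The method: from every read that failed to map contiguously, extract the
two terminal 20-nt anchors and align each independently.  Anchors landing
on one contig/strand in *consecutive* order indicate a linear splice; in
*reversed* order a head-to-tail (back-splice) junction, the signature of a
circular RNA.  Each anchor pair is then extended until the whole read is
covered, enumerating every possible breakpoint, and a junction is reported
only if it survives all seven filters:

1. GT/AG splice signal flanking both splice sites (on the call strand);
2. an unambiguous breakpoint (exactly one valid split of the read);
3. at most two mismatches when extending the anchor alignments;
4. breakpoint at most two nucleotides inside either anchor alignment;
5. at least two independent reads per head-to-tail junction;
6. best-to-second-best anchor alignment score gap of at least 35;
7. at most 100 kb between the two splice sites.

Coordinates: ``donor_pos`` is the half-open exon boundary on the donor
side (the first intronic base after the donor, in genome coordinates for
plus-strand calls), ``acceptor_pos`` the boundary on the acceptor side.
For circular calls the candidate span is ``[min, max)`` of the two
boundaries; on the plus strand ``acceptor_pos < donor_pos`` (the donor is
spliced back to an upstream acceptor); on the minus strand the genomic
inequality mirrors.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment_core import (
    Alignment,
    AnchorHit,
    GenomeIndex,
    NEG_INF,
    QueryScan,
    encode_query,
    revcomp,
    revcomp_codes,
    scan_query,
)
from .config import DetectionConfig, FilterNames

log = logging.getLogger(__name__)

# base codes used in signal checks
_A, _C, _G, _T = 0, 1, 2, 3


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AnchorPairing:
    """One head/tail anchor placement combination, in 'extension frame'.

    If the anchors aligned to the minus strand the frame is the
    reverse-complemented read (so frame coordinates always increase along
    the contig's plus strand); ``frame_strand`` records which.
    """

    read_id: str
    frame_seq: str          # read sequence in extension frame
    contig: str
    head_start: int         # frame head-anchor placement (plus-strand coord)
    tail_start: int
    frame_strand: str       # '+': frame is the read; '-': frame is its revcomp
    orientation: str        # 'consecutive' (linear) or 'reversed' (head-to-tail)
    pair_score: int         # summed anchor placement scores (tie-breaking)


@dataclass
class JunctionCall:
    contig: str
    strand: str
    donor_pos: int
    acceptor_pos: int
    type: str               # 'linear' or 'circular'
    splice_signal: str      # donor+acceptor dinucleotides on the call strand
    mismatches_used: int
    breakpoint_offset_in_read: int  # prefix length, in as-sequenced read coords
    read_id: str = ""
    read_seq: str = ""
    head_gap: int = 0       # filter-6 score gaps of the read's two anchors
    tail_gap: int = 0
    pair_score: int = 0
    pairing: Optional[AnchorPairing] = None

    @property
    def key(self) -> tuple:
        return (self.contig, self.strand, self.donor_pos, self.acceptor_pos)

    @property
    def span(self) -> tuple[int, int]:
        lo, hi = sorted((self.donor_pos, self.acceptor_pos))
        return lo, hi


@dataclass
class CircCandidate:
    contig: str
    start: int
    end: int
    strand: str
    n_reads: int
    n_unique: int
    calls: list[JunctionCall] = field(default_factory=list)
    categories: Optional[set] = None
    spliced_length: Optional[int] = None
    host_gene: Optional[str] = None

    @property
    def donor_pos(self) -> int:
        if self.calls:
            return self.calls[0].donor_pos
        # without calls (e.g. BED round trips) use strand-mirrored span ends
        return self.end if self.strand == "+" else self.start

    @property
    def acceptor_pos(self) -> int:
        if self.calls:
            return self.calls[0].acceptor_pos
        return self.start if self.strand == "+" else self.end

    @property
    def key(self) -> tuple:
        return (self.contig, self.strand, self.donor_pos, self.acceptor_pos)


@dataclass
class Rejection:
    read_id: str
    reason: str


@dataclass
class DiscoveryResult:
    candidates: list[CircCandidate]
    linear_junctions: pd.DataFrame  # contig, strand, donor_pos, acceptor_pos, n_reads
    linear_calls: list[JunctionCall]
    rejections: list[Rejection]
    counters: Counter


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def extract_anchors(read_seq: str, anchor_length: int = 20) -> Optional[tuple[str, str]]:
    """First and last ``anchor_length`` nt of the read, or None if too short."""
    if len(read_seq) < 2 * anchor_length:
        return None
    return read_seq[:anchor_length], read_seq[-anchor_length:]


def pair_anchors(
    head_hits: Sequence[Alignment],
    tail_hits: Sequence[Alignment],
    read_id: str,
    read_seq: str,
    cfg: DetectionConfig,
) -> tuple[list[AnchorPairing], bool]:
    """All same-contig/strand head×tail combinations, distance-filtered.

    Returns (pairings, any_dropped_by_distance).  Minus-strand hit pairs are
    re-expressed in the reverse-complement frame, where the roles of the two
    anchors swap (the read's head anchor is the frame's tail anchor).
    """
    A = cfg.anchor_length
    L = len(read_seq)
    rc = revcomp(read_seq)
    by_key: dict[tuple[str, str], tuple[list[Alignment], list[Alignment]]] = defaultdict(
        lambda: ([], [])
    )
    for h in head_hits:
        by_key[(h.contig, h.strand)][0].append(h)
    for t in tail_hits:
        by_key[(t.contig, t.strand)][1].append(t)

    pairings: list[AnchorPairing] = []
    too_far = False
    for (contig, strand), (hs, ts) in sorted(by_key.items()):
        for h in hs:
            for t in ts:
                if strand == "+":
                    frame_seq, fh, ft = read_seq, h.start, t.start
                else:
                    # rc frame: read tail anchor becomes frame head anchor
                    frame_seq, fh, ft = rc, t.start, h.start
                if fh == ft:
                    continue  # degenerate: would be a contiguous placement
                if abs(ft - fh) > cfg.max_junction_distance + L:
                    too_far = True
                    continue
                orientation = "consecutive" if ft > fh else "reversed"
                pairings.append(
                    AnchorPairing(
                        read_id, frame_seq, contig, fh, ft, strand, orientation,
                        h.score + t.score,
                    )
                )
    pairings.sort(key=lambda p: (p.contig, p.frame_strand, p.head_start, p.tail_start))
    return pairings, too_far


def _signal_ok(codes: np.ndarray, p: int, q: int) -> tuple[bool, bool]:
    """(plus_ok, minus_ok): GT..AG on + needs G,T at p,p+1 and A,G at q-2,q-1;
    on − the same genomic positions must read C,T and A,C."""
    n = len(codes)
    if p + 2 > n or q - 2 < 0 or q > n:
        return False, False
    d0, d1, a0, a1 = codes[p], codes[p + 1], codes[q - 2], codes[q - 1]
    plus = d0 == _G and d1 == _T and a0 == _A and a1 == _G
    minus = d0 == _C and d1 == _T and a0 == _A and a1 == _C
    return bool(plus), bool(minus)


def extend_to_breakpoint(
    pairing: AnchorPairing,
    index: GenomeIndex,
    cfg: DetectionConfig,
) -> JunctionCall | str:
    """Extend an anchor pairing to a unique breakpoint, or return a reason.

    Enumerates every split of the frame read into a prefix (extending the
    frame head anchor rightward) and suffix (extending the frame tail
    anchor leftward): breakpoints ``b`` in
    ``[anchor_len − slack, L − anchor_len + slack]``.  A split is valid if
    extension mismatches (anchor-internal positions are excluded from the
    budget) ≤ the filter-3 budget AND the genome shows a GT/AG signal on
    one strand at the implied splice sites.  Exactly one valid
    (breakpoint, strand) must exist, else the pairing is ambiguous.
    """
    A = cfg.anchor_length
    slack = cfg.breakpoint_slack
    codes = index.codes[pairing.contig]
    n = len(codes)
    seq = encode_query(pairing.frame_seq)
    L = len(seq)
    h, t = pairing.head_start, pairing.tail_start

    b_lo = max(A - slack, 0)
    b_hi = min(L - A + slack, L)  # inclusive

    # prefix mismatches: frame_seq[i] vs codes[h+i]; out-of-contig = mismatch
    pref = np.ones(L, dtype=np.int32)
    hi = min(L, n - h) if h < n else 0
    if h >= 0 and hi > 0:
        g = codes[h : h + hi]
        pref[:hi] = (seq[:hi] != g) | (g == 4)
    pref[:A] = 0  # head-anchor interior is not charged to the budget
    cpref = np.concatenate(([0], np.cumsum(pref)))  # cpref[b] = mism in [0, b)

    # suffix mismatches: frame_seq[i] vs codes[t + A - L + i]
    off = t + A - L
    suf = np.ones(L, dtype=np.int32)
    lo = max(0, -off)
    hi2 = min(L, n - off) if off < n else 0
    if hi2 > lo:
        g = codes[off + lo : off + hi2]
        suf[lo:hi2] = (seq[lo:hi2] != g) | (g == 4)
    suf[L - A :] = 0  # tail-anchor interior
    csuf = np.concatenate(([0], np.cumsum(suf)))
    suf_from = lambda b: csuf[L] - csuf[b]  # mism in [b, L)

    valid: list[tuple[int, str, int, int, int]] = []  # (b, strand, p, q, mm)
    for b in range(b_lo, b_hi + 1):
        p = h + b          # prefix genomic end (half-open)
        q = off + b        # suffix genomic start
        if q == p:
            continue
        if q > p and q - p < cfg.min_intron:
            continue
        if abs(p - q) > cfg.max_junction_distance:
            continue
        mm = int(cpref[b] + suf_from(b))
        if mm > cfg.max_extension_mismatches:
            continue
        plus, minus = _signal_ok(codes, p, q)
        if plus:
            valid.append((b, "+", p, q, mm))
        if minus:
            valid.append((b, "-", p, q, mm))
    if not valid:
        return FilterNames.NO_BREAKPOINT
    if len(valid) > 1:
        return FilterNames.AMBIGUOUS

    b, strand, p, q, mm = valid[0]
    if strand == "+":
        donor, acceptor = p, q
    else:
        donor, acceptor = q, p
    jtype = "linear" if q > p else "circular"
    signal = _signal_string(codes, donor, acceptor, strand)
    # breakpoint offset reported in as-sequenced read coordinates
    b_read = b if pairing.frame_strand == "+" else L - b
    return JunctionCall(
        pairing.contig, strand, donor, acceptor, jtype, signal, mm, b_read,
        pairing.read_id, pairing.frame_seq if pairing.frame_strand == "+" else revcomp(pairing.frame_seq),
        pair_score=pairing.pair_score, pairing=pairing,
    )


_DECODE = "ACGTN"


def _signal_string(codes: np.ndarray, donor: int, acceptor: int, strand: str) -> str:
    if strand == "+":
        d = codes[donor : donor + 2]
        a = codes[acceptor - 2 : acceptor]
        return "".join(_DECODE[c] for c in d) + "".join(_DECODE[c] for c in a)
    d = revcomp_codes(codes[donor - 2 : donor].copy())
    a = revcomp_codes(codes[acceptor : acceptor + 2].copy())
    return "".join(_DECODE[c] for c in d) + "".join(_DECODE[c] for c in a)


def splice_signal(index: GenomeIndex, contig: str, donor: int, acceptor: int, strand: str) -> str:
    """The donor+acceptor dinucleotides on the call strand ('GTAG' if canonical)."""
    return _signal_string(index.codes[contig], donor, acceptor, strand)


# ---------------------------------------------------------------------------
# per-read driver and collation
# ---------------------------------------------------------------------------

def _canonical_seq(seq: str) -> str:
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def process_read(
    read_id: str,
    read_seq: str,
    index: GenomeIndex,
    cfg: DetectionConfig,
    anchor_cache: Optional[dict[str, QueryScan]] = None,
) -> JunctionCall | Rejection:
    """Run one read through anchor extraction → pairing → extension.

    When several distinct pairings survive, the read supports only the one
    with the highest summed anchor placement score; ties discard the read.
    """
    anchors = extract_anchors(read_seq, cfg.anchor_length)
    if anchors is None:
        return Rejection(read_id, FilterNames.TOO_SHORT)
    head, tail = anchors

    def scan(seq: str) -> QueryScan:
        if anchor_cache is not None and seq in anchor_cache:
            return anchor_cache[seq]
        res = scan_query(seq, index, cfg.max_anchor_mismatches, cfg)
        if anchor_cache is not None:
            anchor_cache[seq] = res
        return res

    sh, st = scan(head), scan(tail)
    if not sh.hits or not st.hits:
        return Rejection(read_id, FilterNames.NO_ANCHOR_HIT)
    pairings, too_far = pair_anchors(sh.hits, st.hits, read_id, read_seq, cfg)
    if not pairings:
        return Rejection(read_id, FilterNames.TOO_FAR if too_far else FilterNames.NO_PAIRING)

    calls: list[JunctionCall] = []
    saw_ambiguous = False
    for pairing in pairings:
        res = extend_to_breakpoint(pairing, index, cfg)
        if isinstance(res, JunctionCall):
            calls.append(res)
        elif res == FilterNames.AMBIGUOUS:
            saw_ambiguous = True
    if not calls:
        return Rejection(
            read_id, FilterNames.AMBIGUOUS if saw_ambiguous else FilterNames.NO_BREAKPOINT
        )
    calls.sort(key=lambda c: -c.pair_score)
    if len(calls) > 1 and calls[0].pair_score == calls[1].pair_score:
        return Rejection(read_id, FilterNames.PAIRING_TIE)
    call = calls[0]
    call.head_gap = sh.best_score - sh.second_best_score
    call.tail_gap = st.best_score - st.second_best_score
    return call


def collate_candidates(
    calls: Sequence[JunctionCall],
    cfg: DetectionConfig,
) -> tuple[list[CircCandidate], pd.DataFrame, list[JunctionCall], list[Rejection]]:
    """Apply filters 5 and 6 and group calls into candidates and tables.

    Returns (circ candidates, linear-junction count table, surviving linear
    calls, filter-6 rejections).  Linear junctions get no minimum-read
    filter — they serve as the linear splice-junction read counts.
    """
    kept: list[JunctionCall] = []
    rejections: list[Rejection] = []
    for c in calls:
        if min(c.head_gap, c.tail_gap) < cfg.min_score_gap:
            rejections.append(Rejection(c.read_id, FilterNames.LOW_SCORE_GAP))
        else:
            kept.append(c)

    circ_groups: dict[tuple, list[JunctionCall]] = defaultdict(list)
    linear_groups: dict[tuple, list[JunctionCall]] = defaultdict(list)
    for c in kept:
        (circ_groups if c.type == "circular" else linear_groups)[c.key].append(c)

    candidates: list[CircCandidate] = []
    for key in sorted(circ_groups):
        group = circ_groups[key]
        contig, strand, donor, acceptor = key
        n_reads = len({c.read_id for c in group})
        n_unique = len({_canonical_seq(c.read_seq) for c in group})
        support = n_unique if cfg.require_unique else n_reads
        if support < cfg.min_circ_reads:
            continue
        lo, hi = sorted((donor, acceptor))
        candidates.append(
            CircCandidate(contig, lo, hi, strand, n_reads, n_unique, list(group))
        )

    linear_rows = [
        {
            "contig": k[0], "strand": k[1], "donor_pos": k[2], "acceptor_pos": k[3],
            "n_reads": len({c.read_id for c in g}),
        }
        for k, g in sorted(linear_groups.items())
    ]
    linear_df = pd.DataFrame(
        linear_rows, columns=["contig", "strand", "donor_pos", "acceptor_pos", "n_reads"]
    )
    linear_calls = [c for g in linear_groups.values() for c in g]
    return candidates, linear_df, linear_calls, rejections


def discover(
    reads,
    index: GenomeIndex,
    cfg: Optional[DetectionConfig] = None,
) -> DiscoveryResult:
    """Full junction discovery over a set of (already screened) reads."""
    cfg = cfg or DetectionConfig()
    cache: dict[str, QueryScan] = {}
    calls: list[JunctionCall] = []
    rejections: list[Rejection] = []
    counters: Counter = Counter()
    for r in reads:
        res = process_read(r.read_id, r.sequence, index, cfg, cache)
        if isinstance(res, JunctionCall):
            calls.append(res)
            counters[f"called_{res.type}"] += 1
        else:
            rejections.append(res)
            counters[f"rejected_{res.reason}"] += 1
    candidates, linear_df, linear_calls, gap_rejects = collate_candidates(calls, cfg)
    rejections.extend(gap_rejects)
    counters["rejected_low_score_gap"] = len(gap_rejects)
    counters["n_candidates"] = len(candidates)
    return DiscoveryResult(candidates, linear_df, linear_calls, rejections, counters)


# ---------------------------------------------------------------------------
# independent filter audit
# ---------------------------------------------------------------------------

def reapply_filters(
    candidate: CircCandidate,
    index: GenomeIndex,
    cfg: Optional[DetectionConfig] = None,
) -> dict[str, bool]:
    """Re-check all seven filters for an emitted candidate, independently.

    Used as an idempotence audit: every reported candidate must re-pass
    every filter when they are applied from scratch.
    """
    cfg = cfg or DetectionConfig()
    out: dict[str, bool] = {}
    sig = splice_signal(
        index, candidate.contig, candidate.donor_pos, candidate.acceptor_pos,
        candidate.strand,
    )
    out["f1_gt_ag"] = sig == "GTAG"
    unambiguous = True
    mm_ok = True
    offset_ok = True
    gap_ok = True
    for call in candidate.calls:
        res = extend_to_breakpoint(call.pairing, index, cfg)
        unambiguous &= isinstance(res, JunctionCall)
        mm_ok &= call.mismatches_used <= cfg.max_extension_mismatches
        L = len(call.read_seq)
        lo = cfg.anchor_length - cfg.breakpoint_slack
        hi = L - cfg.anchor_length + cfg.breakpoint_slack
        offset_ok &= lo <= call.breakpoint_offset_in_read <= hi
        head, tail = extract_anchors(call.read_seq, cfg.anchor_length)
        for side in (head, tail):
            scan = scan_query(side, index, cfg.max_anchor_mismatches, cfg)
            gap_ok &= (scan.best_score - scan.second_best_score) >= cfg.min_score_gap
    out["f2_unambiguous"] = unambiguous
    out["f3_mismatches"] = mm_ok
    out["f4_breakpoint_in_anchor"] = offset_ok
    out["f5_min_reads"] = len({c.read_id for c in candidate.calls}) >= cfg.min_circ_reads
    out["f6_score_gap"] = gap_ok
    out["f7_distance"] = (candidate.end - candidate.start) <= cfg.max_junction_distance
    return out
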