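"""Core junction discovery: anchors, pairing geometry, extension, filters."""

import numpy as np
import pytest

from circdetect import alignment_core as ac
from circdetect import junction_discovery as jd
from circdetect.config import DetectionConfig, FilterNames, REJECTION_REASONS
from circdetect.io_formats import Genome
from circdetect.synthetic_data import SimConfig, build_genome, simulate_reads

from conftest import random_sequence

CFG = DetectionConfig()


class TestExtractAnchors:
    def test_100nt_read(self):
        seq = "A" * 20 + "C" * 60 + "G" * 20
        head, tail = jd.extract_anchors(seq)
        assert head == "A" * 20 and tail == "G" * 20

    def test_40nt_boundary_disjoint_adjacent(self):
        seq = "A" * 20 + "G" * 20
        head, tail = jd.extract_anchors(seq)
        assert head == "A" * 20 and tail == "G" * 20

    def test_39nt_skipped(self):
        assert jd.extract_anchors("A" * 39) is None


def _aln(contig, start, strand="+", score=40):
    return ac.Alignment("q", contig, start, start + 20, strand, 0, score)


class TestPairAnchors:
    def test_consecutive_is_linear_candidate(self):
        pairs, _ = jd.pair_anchors(
            [_aln("c1", 1000)], [_aln("c1", 1500)], "r", "A" * 100, CFG
        )
        assert len(pairs) == 1 and pairs[0].orientation == "consecutive"

    def test_reversed_is_circular_candidate(self):
        pairs, _ = jd.pair_anchors(
            [_aln("c1", 5000)], [_aln("c1", 2000)], "r", "A" * 100, CFG
        )
        assert len(pairs) == 1 and pairs[0].orientation == "reversed"

    def test_beyond_100kb_dropped(self):
        pairs, too_far = jd.pair_anchors(
            [_aln("c1", 0)], [_aln("c1", 200_000)], "r", "A" * 100, CFG
        )
        assert pairs == [] and too_far

    def test_cross_contig_hits_never_pair(self):
        pairs, _ = jd.pair_anchors(
            [_aln("c1", 100)], [_aln("c2", 400)], "r", "A" * 100, CFG
        )
        assert pairs == []

    def test_minus_hits_swap_anchor_roles(self):
        pairs, _ = jd.pair_anchors(
            [_aln("c1", 3000, "-")], [_aln("c1", 1000, "-")], "r",
            "A" * 50 + "C" * 50, CFG,
        )
        # in the revcomp frame the read's tail anchor leads
        assert len(pairs) == 1
        p = pairs[0]
        assert p.frame_strand == "-"
        assert p.head_start == 1000 and p.tail_start == 3000
        assert p.orientation == "consecutive"


def build_backsplice_toy(seed=5, read_len=60, overhang=30):
    """300-nt genome with one planted back-splice; returns all pieces.

    The circle spans [100, 200); its donor (at 200) is followed by GT and
    its acceptor (at 100) preceded by AG, so a read wrapping the junction
    has a unique valid breakpoint.
    """
    rng = np.random.default_rng(seed)
    seq = list(random_sequence(rng, 300))
    seq[200:202] = "GT"
    seq[98:100] = "AG"
    genome = Genome({"c1": "".join(seq)})
    circle = genome["c1"][100:200]
    read = circle[-overhang:] + circle[: read_len - overhang]
    return genome, read, 200, 100, overhang


class TestExtendToBreakpoint:
    def oracle_enumeration(self, genome, pairing, cfg):
        """Brute force over all breakpoints, in plain string arithmetic."""
        seq = pairing.frame_seq
        g = genome[pairing.contig]
        L, A = len(seq), cfg.anchor_length
        h, t = pairing.head_start, pairing.tail_start
        valid = []
        for b in range(A - cfg.breakpoint_slack, L - A + cfg.breakpoint_slack + 1):
            p, q = h + b, t + A - L + b
            if q == p or (p < q < p + cfg.min_intron):
                continue
            if abs(p - q) > cfg.max_junction_distance:
                continue
            if q < 2:  # acceptor signal would run off the contig start
                continue
            mm = 0
            for i in range(A, b):  # prefix extension
                if h + i >= len(g) or seq[i] != g[h + i]:
                    mm += 1
            for i in range(b, L - A):  # suffix extension
                gi = t + A - L + i
                if gi < 0 or gi >= len(g) or seq[i] != g[gi]:
                    mm += 1
            if mm > cfg.max_extension_mismatches:
                continue
            for strand, (d0, a0) in (("+", ("GT", "AG")), ("-", ("CT", "AC"))):
                if g[p : p + 2] == d0 and g[q - 2 : q] == a0:
                    valid.append((b, strand, p, q, mm))
        return valid

    def _pairing_for(self, genome, read, cfg):
        index = ac.build_index(genome)
        head, tail = jd.extract_anchors(read, cfg.anchor_length)
        hh = ac.align_ungapped(head, index, cfg.max_anchor_mismatches, cfg)
        th = ac.align_ungapped(tail, index, cfg.max_anchor_mismatches, cfg)
        pairings, _ = jd.pair_anchors(hh, th, "r1", read, cfg)
        assert len(pairings) == 1
        return index, pairings[0]

    def test_matches_bruteforce_on_planted_backsplice(self):
        genome, read, donor, acceptor, overhang = build_backsplice_toy()
        index, pairing = self._pairing_for(genome, read, CFG)
        oracle = self.oracle_enumeration(genome, pairing, CFG)
        assert len(oracle) == 1
        b, strand, p, q, mm = oracle[0]
        call = jd.extend_to_breakpoint(pairing, index, CFG)
        assert isinstance(call, jd.JunctionCall)
        assert (call.donor_pos, call.acceptor_pos) == (donor, acceptor) == (p, q)
        assert call.type == "circular"
        assert call.mismatches_used == mm == 0
        assert call.breakpoint_offset_in_read == b == overhang
        assert call.splice_signal == "GTAG"

    def test_non_gtag_signal_rejected(self):
        genome, read, *_ = build_backsplice_toy()
        seq = list(genome["c1"])
        seq[200] = "C" if seq[200] != "C" else "A"  # break the GT donor
        broken = Genome({"c1": "".join(seq)})
        index, pairing = self._pairing_for(broken, read, CFG)
        assert jd.extend_to_breakpoint(pairing, index, CFG) == FilterNames.NO_BREAKPOINT

    def test_extension_mismatch_budget(self):
        genome, read, donor, acceptor, overhang = build_backsplice_toy()
        # plant three substitutions in the extension region (outside anchors)
        r = list(read)
        for i in (25, 27, 29):
            r[i] = "A" if r[i] != "A" else "C"
        index, pairing = self._pairing_for(genome, "".join(r), CFG)
        assert jd.extend_to_breakpoint(pairing, index, CFG) == FilterNames.NO_BREAKPOINT
        # two substitutions stay within the filter-3 budget
        r = list(read)
        for i in (25, 27):
            r[i] = "A" if r[i] != "A" else "C"
        index, pairing = self._pairing_for(genome, "".join(r), CFG)
        call = jd.extend_to_breakpoint(pairing, index, CFG)
        assert isinstance(call, jd.JunctionCall) and call.mismatches_used == 2

    def test_anchor_internal_mismatches_not_double_counted(self):
        genome, read, donor, acceptor, overhang = build_backsplice_toy()
        r = list(read)
        r[5] = "A" if r[5] != "A" else "C"       # inside head anchor
        r[-5] = "A" if r[-5] != "A" else "C"     # inside tail anchor
        for i in (25, 27):                        # extension region
            r[i] = "A" if r[i] != "A" else "C"
        index, pairing = self._pairing_for(genome, "".join(r), CFG)
        call = jd.extend_to_breakpoint(pairing, index, CFG)
        assert isinstance(call, jd.JunctionCall)
        assert call.mismatches_used == 2  # anchor-internal ones excluded


class TestStrandHandling:
    def test_minus_strand_circle_detected_with_mirrored_boundaries(self):
        cfg = SimConfig(n_genes=8, depth=2000, seed=19, rrna_fraction=0.0)
        genome, models = build_genome(cfg)
        reads, truth = simulate_reads(genome, models, cfg)
        minus = [j for j in truth.circular() if j.strand == "-"]
        assert minus, "fixture should plant at least one minus-strand circle"
        index = ac.build_index(genome)
        j = minus[0]
        spanning = [
            r for r in reads if j.key in truth.reads[r.read_id].spans
        ]
        calls = [
            jd.process_read(r.read_id, r.sequence, index, CFG) for r in spanning
        ]
        good = [c for c in calls if isinstance(c, jd.JunctionCall)]
        assert good and all(c.key == j.key for c in good)
        # minus-strand circle: genomic donor boundary below acceptor boundary
        assert all(c.donor_pos < c.acceptor_pos for c in good)
        assert all(c.splice_signal == "GTAG" for c in good)

    def test_plus_strand_circle_has_acceptor_below_donor(self, tiny_run):
        plus = [c for c in tiny_run.candidates if c.strand == "+"]
        for cand in plus:
            assert cand.acceptor_pos < cand.donor_pos
        linear_plus = [c for c in tiny_run.linear_calls if c.strand == "+"]
        assert all(c.acceptor_pos > c.donor_pos for c in linear_plus)


class TestCollate:
    def _call(self, read_id, key=("c1", "+", 500, 100), jtype="circular",
              seq="ACGT" * 25, gaps=(80, 80)):
        contig, strand, donor, acceptor = key
        c = jd.JunctionCall(contig, strand, donor, acceptor, jtype, "GTAG", 0, 30,
                            read_id, seq)
        c.head_gap, c.tail_gap = gaps
        return c

    def test_single_read_junction_is_not_a_candidate(self):
        cands, _, _, _ = jd.collate_candidates([self._call("r1")], CFG)
        assert cands == []

    def test_two_reads_make_a_candidate(self):
        cands, _, _, _ = jd.collate_candidates(
            [self._call("r1"), self._call("r2")], CFG
        )
        assert len(cands) == 1
        assert cands[0].n_reads == 2
        assert (cands[0].start, cands[0].end) == (100, 500)

    def test_low_score_gap_discards_the_read(self):
        calls = [
            self._call("r1"), self._call("r2"),
            self._call("r3", gaps=(8, 80)),  # 40−32=8 < 35
        ]
        cands, _, _, rejected = jd.collate_candidates(calls, CFG)
        assert cands[0].n_reads == 2
        assert [r.read_id for r in rejected] == ["r3"]
        assert rejected[0].reason == FilterNames.LOW_SCORE_GAP

    def test_unique_read_counter_collapses_duplicates(self):
        calls = [
            self._call("r1", seq="ACGT" * 25),
            self._call("r2", seq="ACGT" * 25),
            self._call("r3", seq="TTAC" * 25),
        ]
        cands, _, _, _ = jd.collate_candidates(calls, CFG)
        assert cands[0].n_reads == 3 and cands[0].n_unique == 2

    def test_linear_junctions_have_no_min_read_filter(self):
        calls = [self._call("r1", key=("c1", "+", 100, 500), jtype="linear")]
        _, linear, _, _ = jd.collate_candidates(calls, CFG)
        assert len(linear) == 1 and linear.iloc[0]["n_reads"] == 1


class TestDiscoveryProperties:
    def test_output_invariant_to_read_order(self, tiny_sim):
        index = ac.build_index(tiny_sim["genome"])
        reads = [r for r in tiny_sim["reads"][:400]]
        fwd = jd.discover(reads, index, CFG)
        rev = jd.discover(list(reversed(reads)), index, CFG)
        assert {c.key: (c.n_reads, c.n_unique) for c in fwd.candidates} == {
            c.key: (c.n_reads, c.n_unique) for c in rev.candidates
        }
        a = fwd.linear_junctions.sort_values(["contig", "donor_pos"]).reset_index(drop=True)
        b = rev.linear_junctions.sort_values(["contig", "donor_pos"]).reset_index(drop=True)
        assert a.equals(b)

    def test_rejection_reasons_come_from_fixed_enumeration(self, tiny_sim):
        index = ac.build_index(tiny_sim["genome"])
        res = jd.discover(tiny_sim["reads"][:600], index, CFG)
        assert {r.reason for r in res.rejections} <= set(REJECTION_REASONS)

    def test_error_free_spanning_reads_reproduce_planted_breakpoints(self, tiny_sim):
        """End-to-end oracle: every junction-spanning read re-aligned by the
        pipeline lands exactly on its planted junction."""
        index = ac.build_index(tiny_sim["genome"])
        truth = tiny_sim["truth"]
        checked = 0
        rejected = 0
        for r in tiny_sim["reads"]:
            spans = truth.reads[r.read_id].spans
            if not spans or checked >= 250:
                continue
            res = jd.process_read(r.read_id, r.sequence, index, CFG)
            if isinstance(res, jd.Rejection):
                # chance multi-mapping ties may remove the odd clean read
                assert res.reason in (FilterNames.AMBIGUOUS, FilterNames.PAIRING_TIE)
                rejected += 1
                continue
            assert res.key in spans
            checked += 1
        assert checked > 100
        assert rejected <= 0.02 * (checked + rejected)
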