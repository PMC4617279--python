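"""Aligner contracts: exhaustive-scan equivalence, scoring, read screens."""

import numpy as np
import pytest

from circdetect import alignment_core as ac
from circdetect.config import DetectionConfig
from circdetect.io_formats import Genome, ReadRecord

from conftest import random_sequence

CFG = DetectionConfig()


def naive_scan(genome: Genome, query: str, max_mm: int):
    """Independent position-by-position oracle (pure Python)."""
    hits = set()
    for strand, q in (("+", query), ("-", ac.revcomp(query))):
        for contig, seq in genome.contigs.items():
            for start in range(len(seq) - len(q) + 1):
                window = seq[start : start + len(q)]
                mm = sum(
                    1 for a, b in zip(q, window) if a != b or a == "N" or b == "N"
                )
                if mm <= max_mm:
                    hits.add((contig, start, strand, mm))
    return hits


class TestAlignUngapped:
    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    def test_matches_naive_oracle(self, rng, max_mm):
        genome = Genome({"c1": random_sequence(rng, 2000)})
        index = ac.build_index(genome)
        for _ in range(40):
            start = int(rng.integers(0, 1980))
            q = list(genome["c1"][start : start + 20])
            # plant up to two mutations
            for _ in range(int(rng.integers(0, 3))):
                p = int(rng.integers(0, 20))
                q[p] = "ACGT"[int(rng.integers(0, 4))]
            query = "".join(q)
            got = {
                (a.contig, a.start, a.strand, a.mismatches)
                for a in ac.align_ungapped(query, index, max_mm)
            }
            assert got == naive_scan(genome, query, max_mm)

    def test_scoring_model(self, rng):
        genome = Genome({"c1": random_sequence(rng, 500)})
        index = ac.build_index(genome)
        q = genome["c1"][100:120]
        perfect = ac.align_ungapped(q, index, 0)[0]
        assert perfect.score == 40  # 20 matches × 2
        mutated = q[:10] + ("A" if q[10] != "A" else "C") + q[11:]
        one_mm = [a for a in ac.align_ungapped(mutated, index, 1) if a.start == 100][0]
        assert one_mm.score == 32  # 19×2 − 6

    def test_strand_symmetry(self, rng):
        genome = Genome({"c1": random_sequence(rng, 1500)})
        index = ac.build_index(genome)
        for _ in range(20):
            s = int(rng.integers(0, 1480))
            q = genome["c1"][s : s + 20]
            fwd = {(a.start, a.strand) for a in ac.align_ungapped(q, index, 1)}
            rev = {(a.start, a.strand) for a in ac.align_ungapped(ac.revcomp(q), index, 1)}
            flip = {"+": "-", "-": "+"}
            assert rev == {(p, flip[st]) for p, st in fwd}

    def test_sorted_by_score_then_position(self, rng):
        genome = Genome({"c1": random_sequence(rng, 300) * 2})  # duplicated
        index = ac.build_index(genome)
        hits = ac.align_ungapped(genome["c1"][50:70], index, 2)
        scores = [h.score for h in hits]
        assert scores == sorted(scores, reverse=True)
        top = [h for h in hits if h.score == scores[0]]
        assert [(h.contig, h.start, h.strand) for h in top] == sorted(
            (h.contig, h.start, h.strand) for h in top
        )


class TestIndex:
    def test_kmer_positions(self):
        genome = Genome({"c1": "ACGTACGT"})
        index = ac.build_index(genome, k=4)
        pos = index.kmer_positions("c1", ac.encode("ACGT"))
        assert sorted(pos.tolist()) == [0, 4]

    def test_kmer_with_n_not_indexed(self):
        genome = Genome({"c1": "ACGTNACGT"})
        index = ac.build_index(genome, k=4)
        # windows containing the N were skipped during construction
        assert sorted(index.kmer_positions("c1", ac.encode("ACGT")).tolist()) == [0, 5]

    def test_palindromic_hit_on_both_strands(self):
        genome = Genome({"c1": "AAACGTAA"})
        index = ac.build_index(genome, k=4)
        hits = ac.align_ungapped("ACGT", index, 0)
        assert {(h.start, h.strand) for h in hits} == {(2, "+"), (2, "-")}

    def test_n_in_query_never_matches(self, rng):
        genome = Genome({"c1": "ACGTN" + random_sequence(rng, 100)})
        index = ac.build_index(genome)
        hits = ac.align_ungapped("ACGTN" + genome["c1"][5:20], index, 0)
        assert hits == []  # N≠N by contract


class TestScreens:
    def test_all_rrna_reads_removed(self, rng):
        decoy = Genome({"rRNA_1": random_sequence(rng, 800)})
        idx = ac.build_index(decoy)
        reads = [
            ReadRecord(f"r{i}", decoy["rRNA_1"][s : s + 100])
            for i, s in enumerate(rng.integers(0, 700, 20))
        ]
        kept, frac = ac.fraction_rrna(reads, idx)
        assert frac == 1.0 and kept == []

    def test_no_reference_keeps_everything(self, rng):
        reads = [ReadRecord("r1", random_sequence(rng, 100))]
        kept, frac = ac.fraction_rrna(reads, None)
        assert frac == 0.0 and len(kept) == 1

    def test_simulated_rrna_fraction_recovered_exactly(self, tiny_sim):
        kept, frac = ac.fraction_rrna(
            tiny_sim["reads"], ac.build_index(tiny_sim["rrna"]), 2
        )
        truth_frac = sum(
            1 for o in tiny_sim["truth"].reads.values() if o.kind == "rrna"
        ) / len(tiny_sim["reads"])
        assert frac == pytest.approx(truth_frac, abs=0)

    def test_exonic_read_dropped_junction_read_kept(self, tiny_sim):
        idx = ac.build_index(tiny_sim["genome"])
        truth = tiny_sim["truth"]
        exonic = next(
            r for r in tiny_sim["reads"]
            if truth.reads[r.read_id].kind == "linear" and not truth.reads[r.read_id].spans
        )
        spanning = next(
            r for r in tiny_sim["reads"] if truth.reads[r.read_id].spans
        )
        unmapped, mapped = ac.drop_contiguous([exonic, spanning], idx)
        assert [a.query_id for a in mapped] == [exonic.read_id]
        assert [r.read_id for r in unmapped] == [spanning.read_id]

    def test_two_mismatch_read_still_dropped(self, rng):
        genome = Genome({"c1": random_sequence(rng, 2000)})
        idx = ac.build_index(genome)
        seq = list(genome["c1"][500:600])
        seq[10] = "A" if seq[10] != "A" else "C"
        seq[90] = "A" if seq[90] != "A" else "C"
        unmapped, mapped = ac.drop_contiguous([ReadRecord("r", "".join(seq))], idx)
        assert len(mapped) == 1 and mapped[0].mismatches == 2


class TestSamInterchange:
    def test_roundtrip(self, rng, tmp_path):
        genome = Genome({"c1": random_sequence(rng, 400)})
        alns = [
            ac.Alignment("r1", "c1", 10, 30, "+", 0, 40),
            ac.Alignment("r2", "c1", 50, 70, "-", 1, 32),
        ]
        path = str(tmp_path / "a.sam")
        ac.alignments_to_sam(alns, genome, path)
        assert ac.alignments_from_sam(path) == alns

    def test_gapped_records_skipped(self, tmp_path):
        sam = (
            "@HD\tVN:1.6\n@SQ\tSN:c1\tLN:400\n"
            "r1\t0\tc1\t11\t255\t20M\t*\t0\t0\t" + "A" * 20 + "\t*\tNM:i:0\n"
            "r2\t0\tc1\t51\t255\t10M2D10M\t*\t0\t0\t" + "A" * 20 + "\t*\tNM:i:2\n"
        )
        p = tmp_path / "g.sam"
        p.write_text(sam)
        alns = ac.alignments_from_sam(str(p))
        assert [a.query_id for a in alns] == ["r1"]

    def test_sam_path_reproduces_contiguous_screen(self, tiny_sim, tmp_path):
        """Alignments exported to SAM and re-ingested are interchangeable
        with the internal aligner's output."""
        idx = ac.build_index(tiny_sim["genome"])
        reads = tiny_sim["reads"][:300]
        _, mapped = ac.drop_contiguous(reads, idx)
        path = str(tmp_path / "m.sam")
        ac.alignments_to_sam(mapped, tiny_sim["genome"], path)
        assert ac.alignments_from_sam(path) == mapped
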