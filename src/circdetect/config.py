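"""Pipeline-wide defaults and dialect tables.

Every numeric threshold of the detection method is a named field here so a
run is fully described by one :class:`DetectionConfig` instance (and a seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json

#: GTF ``gene_biotype`` dialect → internal biotype bucket.  ENSEMBL release
#: dialects spell the long-non-coding bucket several ways (``lincRNA``,
#: ``antisense`` …); anything unknown falls into ``other``.
BIOTYPE_BUCKETS: dict[str, str] = {
    "protein_coding": "protein_coding",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
    "processed_transcript": "lncRNA",
    "sense_intronic": "lncRNA",
    "sense_overlapping": "lncRNA",
    "3prime_overlapping_ncrna": "lncRNA",
    "miRNA": "miRNA",
}

VALID_BIOTYPES = ("protein_coding", "lncRNA", "miRNA", "other")


def biotype_bucket(raw: str) -> str:
    """Map a raw GTF biotype string to one of :data:`VALID_BIOTYPES`."""
    return BIOTYPE_BUCKETS.get(raw, "other")


@dataclass
class DetectionConfig:
    """All tunables of the junction-discovery method.

    Defaults follow the published filter set: 20-nt anchors, at most two
    mismatches for the rRNA / contiguous-mapping screens and for anchor
    extension, a breakpoint allowed at most two nucleotides inside either
    anchor alignment, a minimum best-to-second-best anchor score gap of 35,
    at most 100 kb between the two splice sites, and at least two
    independent reads per head-to-tail junction.
    """

    anchor_length: int = 20
    max_anchor_mismatches: int = 2      # budget when listing anchor placements
    rrna_mismatches: int = 2            # end-to-end budget for the rRNA screen
    contiguous_mismatches: int = 2      # end-to-end budget for genome screen
    max_extension_mismatches: int = 2   # filter 3
    breakpoint_slack: int = 2           # filter 4
    min_score_gap: int = 35             # filter 6
    max_junction_distance: int = 100_000  # filter 7
    min_circ_reads: int = 2             # filter 5
    require_unique: bool = False        # filter 5 on distinct sequences instead
    match_score: int = 2
    mismatch_penalty: int = 6
    min_intron: int = 4                 # room for non-overlapping GT..AG
    seed_k: int = 12                    # exact-seed length for read screening

    def score(self, length: int, mismatches: int) -> int:
        """Ungapped end-to-end alignment score: 2·matches − 6·mismatches."""
        return self.match_score * (length - mismatches) - self.mismatch_penalty * mismatches

    def config_hash(self) -> str:
        """Stable short hash of all settings, recorded in output headers."""
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


@dataclass
class QuantConfig:
    """Quantification settings: pseudocounts and the linear-median rule."""

    pseudocount: int = 1
    per_million: float = 1_000_000.0
    detected_only: bool = False  # median over detected junctions only

@dataclass
class FilterNames:
    """The fixed rejection-reason enumeration used in rejected-read tables."""

    TOO_SHORT = "too_short"
    NO_ANCHOR_HIT = "no_anchor_hit"
    NO_PAIRING = "no_pairing"
    TOO_FAR = "too_far"
    NO_BREAKPOINT = "no_breakpoint"
    AMBIGUOUS = "ambiguous"
    LOW_SCORE_GAP = "low_score_gap"
    PAIRING_TIE = "pairing_tie"


REJECTION_REASONS = (
    FilterNames.TOO_SHORT,
    FilterNames.NO_ANCHOR_HIT,
    FilterNames.NO_PAIRING,
    FilterNames.TOO_FAR,
    FilterNames.NO_BREAKPOINT,
    FilterNames.AMBIGUOUS,
    FilterNames.LOW_SCORE_GAP,
    FilterNames.PAIRING_TIE,
)
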