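"""Record types shared by the quantification stage."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class ExpressionRecord:
    """One feature's raw and depth-normalized expression.

    ``normalized`` is reads per million protein-coding-mapped reads for
    circRNA features, or TPM for genes.
    """

    feature_id: str
    raw_count: int
    normalized: float


@dataclass
class RatioRecord:
    """Circular-to-linear expression ratio with pseudocounts.

    ratio = (head_to_tail_reads + 1) / (median_linear_reads + 1).
    """

    circ_id: str
    head_to_tail_reads: int
    median_linear_reads: float
    ratio: float
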