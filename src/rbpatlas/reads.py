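"""Alignment-derived read-pair records.

A record summarises one mapping of a read pair: target (chromosome or
repeat transcript), 0-based half-open mate span, UMI, pair-summed alignment
score (higher is better) and mismatch count.  Spliced reads may carry
``blocks``, the exonic segments of the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass
class ReadRecord:
    read_id: str
    umi: str
    start: int
    stop: int
    strand: str = "+"
    target: str = "chrS"
    alignment_score: int = 0
    mismatches: int = 0
    blocks: Optional[tuple[tuple[int, int], ...]] = None

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError(
                f"{self.read_id}: start {self.start} must be < stop {self.stop}"
            )
        if self.strand not in "+-":
            raise ValueError(f"{self.read_id}: bad strand {self.strand!r}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.stop)


TSV_COLUMNS = [
    "read_id", "umi", "start", "stop", "strand",
    "target", "alignment_score", "mismatches",
]
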