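"""Gene models, transcript region tracks, and the repeat-family database.

Coordinates are 0-based half-open on a single synthetic chromosome (BED
convention).  Region labels follow the 11-class vocabulary used for peak
annotation: tRNA, miRNA, miRNA-proximal, CDS, 3'UTR, 5'UTR, 5'ss, 3'ss,
proximal intron, distal intron and noncoding exonic; peaks outside every
gene fall back to "intergenic".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from intervaltree import IntervalTree

# Region label vocabulary -------------------------------------------------

TRNA = "tRNA"
MIRNA = "miRNA"
MIRNA_PROXIMAL = "miRNA-proximal"
CDS = "CDS"
UTR3 = "3'UTR"
UTR5 = "5'UTR"
SS5 = "5'ss"
SS3 = "3'ss"
PROX_INTRON = "proximal intron"
DIST_INTRON = "distal intron"
NONCODING_EXON = "noncoding exonic"
INTERGENIC = "intergenic"

REGION_LABELS = [
    TRNA, MIRNA, MIRNA_PROXIMAL, CDS, UTR3, UTR5,
    SS5, SS3, PROX_INTRON, DIST_INTRON, NONCODING_EXON,
]

#: priority when a peak overlaps several region types of a single gene
WITHIN_GENE_PRIORITY = [
    TRNA, MIRNA, MIRNA_PROXIMAL, CDS, UTR3, UTR5,
    SS5, SS3, PROX_INTRON, DIST_INTRON, NONCODING_EXON,
]

#: priority when a peak overlaps several genes (applied to each gene's label)
CROSS_GENE_PRIORITY = [
    TRNA, MIRNA, CDS, UTR3, UTR5, MIRNA_PROXIMAL,
    NONCODING_EXON, SS5, SS3, PROX_INTRON, DIST_INTRON,
]

SPLICE_SITE_WINDOW = 100  # nt of intron adjacent to an exon
PROXIMAL_WINDOW = 500  # nt of intron within "proximal" distance of a splice site
MIRNA_PROXIMAL_WINDOW = 500


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]]
    cds: Optional[tuple[int, int]] = None  # genomic span of the coding region

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = -1
        for s, e in self.exons:
            if not s < e:
                raise ValueError(f"{self.transcript_id}: empty exon [{s},{e})")
            if s < prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GeneModel:
    gene_id: str
    gene_type: str  # protein_coding | tRNA | miRNA | noncoding
    chrom: str
    strand: str
    transcripts: list[Transcript]
    tpm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for cell, v in self.tpm.items():
            if v < 0:
                raise ValueError(f"{self.gene_id}: negative TPM for {cell}")

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def representative_transcript(
        self, transcript_tpm: Optional[dict[str, float]] = None
    ) -> Transcript:
        """Highest-expressed isoform; ties (and no table) break lexicographically."""
        if transcript_tpm:
            return max(
                self.transcripts,
                key=lambda t: (transcript_tpm.get(t.transcript_id, 0.0), t.transcript_id),
            )
        return min(self.transcripts, key=lambda t: t.transcript_id)


def _clip(s: int, e: int, lo: int, hi: int) -> Optional[tuple[int, int]]:
    s, e = max(s, lo), min(e, hi)
    return (s, e) if s < e else None


def transcript_region_intervals(
    gene: GeneModel, transcript: Transcript
) -> list[tuple[int, int, str]]:
    """Labelled (start, end, label) intervals for one isoform.

    Intervals may overlap (e.g. a splice-site window lies inside the
    proximal-intron window); the annotation priority order resolves them.
    """
    out: list[tuple[int, int, str]] = []
    if gene.gene_type == "tRNA":
        return [(s, e, TRNA) for s, e in transcript.exons]
    if gene.gene_type == "miRNA":
        out = [(s, e, MIRNA) for s, e in transcript.exons]
        out.append(
            (max(0, transcript.start - MIRNA_PROXIMAL_WINDOW), transcript.start, MIRNA_PROXIMAL)
        )
        out.append((transcript.end, transcript.end + MIRNA_PROXIMAL_WINDOW, MIRNA_PROXIMAL))
        return out

    # exonic labels
    if gene.gene_type == "protein_coding" and transcript.cds is not None:
        cs, ce = transcript.cds
        left_utr = UTR5 if gene.strand == "+" else UTR3
        right_utr = UTR3 if gene.strand == "+" else UTR5
        for s, e in transcript.exons:
            piece = _clip(s, e, 0, cs)
            if piece:
                out.append((*piece, left_utr))
            piece = _clip(s, e, cs, ce)
            if piece:
                out.append((*piece, CDS))
            piece = _clip(s, e, ce, 10**18)
            if piece:
                out.append((*piece, right_utr))
    else:
        out.extend((s, e, NONCODING_EXON) for s, e in transcript.exons)

    # intronic labels
    for i_s, i_e in transcript.introns:
        # donor (5'ss) side is the transcript-upstream end of the intron
        if gene.strand == "+":
            donor = (i_s, min(i_s + SPLICE_SITE_WINDOW, i_e), SS5)
            acceptor = (max(i_e - SPLICE_SITE_WINDOW, i_s), i_e, SS3)
        else:
            donor = (max(i_e - SPLICE_SITE_WINDOW, i_s), i_e, SS5)
            acceptor = (i_s, min(i_s + SPLICE_SITE_WINDOW, i_e), SS3)
        out.append(donor)
        out.append(acceptor)
        out.append((i_s, min(i_s + PROXIMAL_WINDOW, i_e), PROX_INTRON))
        out.append((max(i_e - PROXIMAL_WINDOW, i_s), i_e, PROX_INTRON))
        if i_e - i_s > 2 * PROXIMAL_WINDOW:
            out.append((i_s + PROXIMAL_WINDOW, i_e - PROXIMAL_WINDOW, DIST_INTRON))
    return out


class Annotation:
    """A synthetic chromosome: sequence, gene models, and region lookup trees."""

    def __init__(self, chrom: str, length: int, genes: list[GeneModel], sequence=None):
        self.chrom = chrom
        self.length = length
        self.genes = list(genes)
        self.sequence = sequence  # int8 array (kmers encoding) or None
        self._trees: dict[str, IntervalTree] = {"+": IntervalTree(), "-": IntervalTree()}
        self._gene_index: dict[str, GeneModel] = {}
        for g in self.genes:
            self._gene_index[g.gene_id] = g
            for t in g.transcripts:
                for s, e, label in transcript_region_intervals(g, t):
                    s, e = max(0, s), min(e, length)
                    if s < e:
                        self._trees[g.strand].addi(s, e, (g.gene_id, label))

    def gene(self, gene_id: str) -> GeneModel:
        return self._gene_index[gene_id]

    def overlapping_regions(
        self, start: int, end: int, strand: str
    ) -> dict[str, set[str]]:
        """gene_id -> set of region labels overlapped by [start, end) on strand."""
        hits: dict[str, set[str]] = {}
        for iv in self._trees[strand].overlap(start, end):
            gene_id, label = iv.data
            hits.setdefault(gene_id, set()).add(label)
        return hits

    def region_sequence(self, start: int, end: int, strand: str) -> str:
        from . import kmers

        if self.sequence is None:
            raise ValueError("annotation carries no sequence")
        seq = self.sequence[max(0, start) : min(end, self.length)]
        if strand == "-":
            seq = (3 - seq)[::-1]  # reverse complement in ACGU coding
        return kmers.decode(seq)


# Repeat-family database --------------------------------------------------


@dataclass
class RepeatTranscript:
    transcript_id: str
    family_id: str
    priority: int  # 1 = primary transcript, larger = pseudogenes
    length: int

    def __post_init__(self) -> None:
        if self.priority < 1:
            raise ValueError("priority must be >= 1")
        if self.length < 1:
            raise ValueError("length must be >= 1")


class RepeatFamilyDB:
    """Multi-copy element families with per-transcript mapping priorities.

    Reverse-strand mappings belong to a distinct antisense counterpart of
    each family, except for simple-repeat families, which are combined.
    """

    ANTISENSE_PREFIX = "antisense "

    def __init__(
        self,
        transcripts: Iterable[RepeatTranscript],
        simple_repeat_families: Iterable[str] = (),
    ):
        self.transcripts: dict[str, RepeatTranscript] = {}
        self.families: dict[str, list[RepeatTranscript]] = {}
        self.simple_repeat_families = set(simple_repeat_families)
        for t in transcripts:
            if t.transcript_id in self.transcripts:
                raise ValueError(f"duplicate transcript {t.transcript_id}")
            self.transcripts[t.transcript_id] = t
            self.families.setdefault(t.family_id, []).append(t)
        for fam, members in self.families.items():
            prios = [m.priority for m in members]
            if len(set(prios)) != len(prios):
                raise ValueError(f"family {fam}: priorities not unique")

    def family_for(self, transcript_id: str, strand: str = "+") -> str:
        fam = self.transcripts[transcript_id].family_id
        if strand == "-" and fam not in self.simple_repeat_families:
            return self.ANTISENSE_PREFIX + fam
        return fam

    def priority(self, transcript_id: str) -> int:
        return self.transcripts[transcript_id].priority

    def primary_transcript(self, family_id: str) -> RepeatTranscript:
        return min(self.families[family_id], key=lambda t: t.priority)

    def family_ids(self, include_antisense: bool = False) -> list[str]:
        fams = sorted(self.families)
        if include_antisense:
            fams += [
                self.ANTISENSE_PREFIX + f
                for f in sorted(self.families)
                if f not in self.simple_repeat_families
            ]
        return fams
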