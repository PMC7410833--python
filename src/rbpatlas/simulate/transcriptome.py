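"""Synthetic chromosome builder: gene models plus a repeat-family database.

The layout guarantees that every region label used by peak annotation is
instantiated at least once (tRNA, miRNA, miRNA-proximal, CDS, UTRs, splice
sites, proximal and distal introns, noncoding exons) and that the repeat
database contains a primary transcript with lower-priority pseudogenes, an
antisense counterpart (implicit for every non-simple family) and one
simple-repeat family.
"""

from __future__ import annotations

import numpy as np

from ..annotation import Annotation, GeneModel, RepeatFamilyDB, RepeatTranscript, Transcript

CELLS = ("cellA", "cellB")
CHROM = "chrS"


def _protein_coding_gene(idx: int, cursor: int, strand: str, rng) -> GeneModel:
    n_exons = int(rng.integers(3, 7))
    exons = []
    pos = cursor
    for j in range(n_exons):
        elen = int(rng.integers(120, 320))
        exons.append((pos, pos + elen))
        pos += elen
        if j < n_exons - 1:
            # mix of short and long introns so both proximal-only and
            # distal-containing introns occur
            ilen = int(rng.integers(1200, 2600)) if j % 2 == 0 else int(rng.integers(300, 900))
            pos += ilen
    # CDS from inside the first exon to inside the last exon -> both UTRs exist
    cds_start = exons[0][0] + (exons[0][1] - exons[0][0]) // 2
    cds_end = exons[-1][0] + (exons[-1][1] - exons[-1][0]) // 2
    gid = f"G{idx:04d}"
    tx = [Transcript(f"{gid}.t1", exons, cds=(cds_start, cds_end))]
    if n_exons >= 4 and rng.random() < 0.4:
        # second isoform skipping one internal exon, shifted stop codon:
        # creates within-gene CDS / 3'UTR conflicts for the annotator
        skip = int(rng.integers(1, n_exons - 1))
        exons2 = [e for j, e in enumerate(exons) if j != skip]
        cds_end2 = exons2[-2][1] if len(exons2) >= 2 else cds_end
        tx.append(Transcript(f"{gid}.t2", exons2, cds=(cds_start, min(cds_end2, cds_end))))
    tpm = {c: float(rng.lognormal(2.5, 1.0)) for c in CELLS}
    return GeneModel(gid, "protein_coding", CHROM, strand, tx, tpm)


def _small_gene(idx: int, cursor: int, gene_type: str, length: int, rng) -> GeneModel:
    gid = f"G{idx:04d}"
    tx = Transcript(f"{gid}.t1", [(cursor, cursor + length)])
    tpm = {c: float(rng.lognormal(1.0, 0.5)) for c in CELLS}
    return GeneModel(gid, gene_type, CHROM, "+" if rng.random() < 0.5 else "-", [tx], tpm)


def _noncoding_gene(idx: int, cursor: int, rng) -> GeneModel:
    gid = f"G{idx:04d}"
    e1 = (cursor, cursor + int(rng.integers(150, 400)))
    gap = int(rng.integers(300, 800))
    s2 = e1[1] + gap
    e2 = (s2, s2 + int(rng.integers(150, 400)))
    tx = Transcript(f"{gid}.t1", [e1, e2])
    tpm = {c: float(rng.lognormal(1.5, 0.8)) for c in CELLS}
    return GeneModel(gid, "noncoding", CHROM, "+" if rng.random() < 0.5 else "-", [tx], tpm)


def _repeat_db(n_repeat_families: int, rng) -> RepeatFamilyDB:
    transcripts = []
    names = ["RNA18S", "Alu", "L1", "RNA28S", "snRNA-U2"]
    for i in range(n_repeat_families):
        fam = names[i] if i < len(names) else f"RF{i:02d}"
        primary_len = int(rng.integers(800, 2000))
        transcripts.append(RepeatTranscript(f"{fam}_primary", fam, 1, primary_len))
        for p in range(2, 4):
            transcripts.append(
                RepeatTranscript(
                    f"{fam}_pseudo{p - 1}", fam, p, int(rng.integers(300, primary_len))
                )
            )
    for j in range(3):
        transcripts.append(RepeatTranscript(f"SR_{j}", "simple repeat", j + 1, 60))
    return RepeatFamilyDB(transcripts, simple_repeat_families={"simple repeat"})


def make_transcriptome(
    n_genes: int, n_repeat_families: int = 5, seed: int = 0
) -> tuple[Annotation, RepeatFamilyDB]:
    """Build a deterministic synthetic annotation and repeat database.

    Parameters
    ----------
    n_genes : total number of genes laid out on one linear chromosome.
    n_repeat_families : number of multi-copy families besides the single
        combined simple-repeat family.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_repeat_families < 1:
        raise ValueError("n_repeat_families must be >= 1")
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    cursor = 2000
    for idx in range(n_genes):
        # first four slots guarantee label coverage, remainder mostly coding
        if idx == 1 and n_genes >= 2:
            g = _small_gene(idx, cursor, "tRNA", 80, rng)
        elif idx == 2 and n_genes >= 3:
            g = _small_gene(idx, cursor, "miRNA", 90, rng)
        elif idx == 3 and n_genes >= 4:
            g = _noncoding_gene(idx, cursor, rng)
        elif idx > 3 and rng.random() < 0.08:
            g = _noncoding_gene(idx, cursor, rng)
        else:
            strand = "+" if rng.random() < 0.6 else "-"
            g = _protein_coding_gene(idx, cursor, strand, rng)
        genes.append(g)
        cursor = g.end + int(rng.integers(2000, 5000))
    length = cursor + 2000
    sequence = rng.integers(0, 4, size=length).astype(np.int8)
    annotation = Annotation(CHROM, length, genes, sequence=sequence)
    db = _repeat_db(n_repeat_families, rng)
    return annotation, db
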