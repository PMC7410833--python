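"""eCLIP read simulator: two IP replicates and one size-matched input.

Input reads are sampled proportionally to expression x length across gene
models plus a baseline abundance for repeat-family transcripts.  IP reads
re-weight the same units by the planted family selection weights, and by
the planted fold enrichment (lambda) wherever a fragment overlaps a
planted element (enforced exactly by acceptance sampling, so observed
IP/input density ratios recover lambda).  PCR duplicates are created by
copying full records - identical coordinates and UMI - so the dedup key of
(start, stop, UMI) finds them.
"""

from __future__ import annotations

import numpy as np

from ..annotation import Annotation, RepeatFamilyDB
from ..kmers import encode
from ..reads import ReadRecord
from .truth import BindingTruth

UMI_LENGTH = 10
READ_LENGTH = 50
REPEAT_BASE_TPM = 30.0


def _umis(n: int, rng) -> list[str]:
    letters = np.array(list("ACGT"))
    arr = rng.integers(0, 4, size=(n, UMI_LENGTH))
    return ["".join(row) for row in letters[arr]]


def _lambda_at(starts: np.ndarray, read_len: int, elements) -> np.ndarray:
    lam = np.ones(len(starts))
    for s, e, fold in elements:
        hit = (starts < e) & (starts + read_len > s)
        lam[hit] = np.maximum(lam[hit], fold)
    return lam


def _simulate_library(
    annotation: Annotation,
    db: RepeatFamilyDB | None,
    truth: BindingTruth,
    depth: int,
    dup_rate: float,
    rng,
    is_ip: bool,
    cell: str,
    read_len: int,
    prefix: str,
) -> list[ReadRecord]:
    units: list[tuple[str, object, float, float]] = []  # (kind, obj, weight, lam_max)
    for g in annotation.genes:
        w = g.tpm.get(cell, 0.0) * (g.end - g.start)
        if w <= 0:
            continue
        lam_max = 1.0
        if is_ip:
            for s, e, fold in truth.enriched_elements:
                if s < g.end and e > g.start:
                    lam_max = max(lam_max, fold)
        units.append(("gene", g, w * lam_max, lam_max))
    if db is not None:
        for fam in db.family_ids():
            t = db.primary_transcript(fam)
            w = REPEAT_BASE_TPM * t.length
            if is_ip:
                w *= truth.family_weights.get(fam, 1.0)
            units.append(("repeat", t, w, 1.0))

    if depth == 0 or not units:
        return []
    weights = np.array([u[2] for u in units])
    probs = weights / weights.sum()
    lo = np.array(
        [u[1].start if u[0] == "gene" else 0 for u in units], dtype=np.int64
    )
    hi = np.array(
        [
            max(u[1].start + 1, u[1].end - read_len)
            if u[0] == "gene"
            else max(1, u[1].length - read_len)
            for u in units
        ],
        dtype=np.int64,
    )
    lam_max = np.array([u[3] for u in units])
    targets = np.array(
        [annotation.chrom if u[0] == "gene" else u[1].transcript_id for u in units]
    )
    strands = np.array(
        [u[1].strand if u[0] == "gene" else "+" for u in units]
    )

    records: list[ReadRecord] = []
    i_read = 0
    while len(records) < depth:
        batch = max(1024, int((depth - len(records)) * 1.2))
        idx = rng.choice(len(units), size=batch, p=probs)
        starts = lo[idx] + (rng.random(batch) * (hi[idx] - lo[idx])).astype(np.int64)
        # acceptance step keeps IP density exactly proportional to lambda
        keep = np.ones(batch, dtype=bool)
        if is_ip and truth.enriched_elements:
            boost = lam_max[idx] > 1.0
            lam = np.ones(batch)
            lam[boost] = _lambda_at(starts[boost], read_len, truth.enriched_elements)
            keep = rng.random(batch) < lam / lam_max[idx]
        umis = _umis(batch, rng)
        mism = rng.poisson(0.3, size=batch)
        for j in np.nonzero(keep)[0]:
            records.append(
                ReadRecord(
                    read_id=f"{prefix}_{i_read}",
                    umi=umis[j],
                    start=int(starts[j]),
                    stop=int(starts[j]) + read_len,
                    strand=str(strands[idx[j]]),
                    target=str(targets[idx[j]]),
                    alignment_score=88 - 6 * int(mism[j]),
                    mismatches=int(mism[j]),
                )
            )
            i_read += 1
            if len(records) >= depth:
                break

    if dup_rate > 0:
        dup = rng.random(len(records)) < dup_rate
        for j in np.nonzero(dup)[0]:
            r = records[j]
            records.append(
                ReadRecord(
                    read_id=f"{r.read_id}_dup",
                    umi=r.umi,
                    start=r.start,
                    stop=r.stop,
                    strand=r.strand,
                    target=r.target,
                    alignment_score=r.alignment_score,
                    mismatches=r.mismatches,
                )
            )
    return records


def simulate_eclip(
    annotation: Annotation,
    truth: BindingTruth,
    depth: int,
    dup_rate: float = 0.1,
    seed: int = 0,
    db: RepeatFamilyDB | None = None,
    cell: str = "cellA",
    read_length: int = READ_LENGTH,
) -> tuple[list[ReadRecord], list[ReadRecord], list[ReadRecord]]:
    """Simulate (IP rep1, IP rep2, input) read sets.

    ``depth`` is the number of unique molecules per library before PCR
    duplication; with duplication rate d the library holds ~depth*(1+d)
    records.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not 0 <= dup_rate < 1:
        raise ValueError("dup_rate must be in [0, 1)")
    rng1, rng2, rng_in = np.random.default_rng(seed).spawn(3)
    rep1 = _simulate_library(
        annotation, db, truth, depth, dup_rate, rng1, True, cell, read_length, "ip1"
    )
    rep2 = _simulate_library(
        annotation, db, truth, depth, dup_rate, rng2, True, cell, read_length, "ip2"
    )
    inp = _simulate_library(
        annotation, db, truth, depth, dup_rate, rng_in, False, cell, read_length, "in"
    )
    return rep1, rep2, inp


def coverage_from_records(
    records, length: int, target: str | None = None
) -> tuple[np.ndarray, int]:
    """Base-level read coverage over [0, length); returns (coverage, n_reads)."""
    diff = np.zeros(length + 1)
    n = 0
    for r in records:
        if target is not None and r.target != target:
            continue
        diff[min(r.start, length)] += 1
        diff[min(r.stop, length)] -= 1
        n += 1
    return np.cumsum(diff[:-1]), n


def plant_motif_in_sequence(
    annotation: Annotation,
    intervals,
    motif: str,
    spacing: int = 30,
) -> None:
    """Embed ``motif`` repeatedly within (start, end, strand) intervals.

    On '-' strand intervals the reverse complement is written so that the
    transcribed (sense) sequence carries the motif.
    """
    enc = encode(motif)
    rc = (3 - enc)[::-1]
    for start, end, strand in intervals:
        word = enc if strand == "+" else rc
        pos = start
        while pos + len(word) <= min(end, annotation.length):
            annotation.sequence[pos : pos + len(word)] = word
            pos += spacing
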