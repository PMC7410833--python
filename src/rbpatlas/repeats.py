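"""Family-aware quantification of reads mapping to multi-copy elements.

Read pairs that map to a repeat database are kept only at their lowest
mismatch score; equal-scoring mappings within one family resolve to the
highest-priority transcript, while pairs whose best score spans two or
more families are discarded.  Unique genomic mappings beat the repeat
mapping only when their pair alignment score is better by strictly more
than 24 (two mismatches per read).  PCR duplicates are collapsed on the
(target, start, stop, UMI) key, and per-element signal is summarised as
relative information p_i * log2(p_i / q_i), where p_i and q_i are the
fractions of total reads in IP and input mapping to element i.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import RepeatFamilyDB
from .reads import ReadRecord

SCORE_MARGIN = 24  # pair alignment score: two mismatches per read


@dataclass
class FamilyAssignment:
    family_id: str
    transcript_id: str
    record: ReadRecord


def assign_family(
    mappings: Sequence[ReadRecord], db: RepeatFamilyDB
) -> Optional[FamilyAssignment]:
    """Assign one read pair's repeat mappings to a family, or discard.

    Returns None both for an empty mapping list and for pairs whose best
    mismatch score spans more than one family (sense and antisense count
    as distinct families).
    """
    if not mappings:
        return None
    ids = {m.read_id for m in mappings}
    if len(ids) != 1:
        raise ValueError(f"mappings from several read pairs: {sorted(ids)}")
    best = min(m.mismatches for m in mappings)
    top = [m for m in mappings if m.mismatches == best]
    families = {db.family_for(m.target, m.strand) for m in top}
    if len(families) != 1:
        return None
    primary = min(top, key=lambda m: db.priority(m.target))
    return FamilyAssignment(families.pop(), primary.target, primary)


def reconcile_unique_vs_repeat(
    genomic: ReadRecord, repeat: ReadRecord
) -> ReadRecord:
    """Keep the genomic mapping only when it beats the repeat mapping by
    strictly more than the 24-point pair-score margin."""
    if genomic.read_id != repeat.read_id:
        raise ValueError(
            f"read ids differ: {genomic.read_id!r} vs {repeat.read_id!r}"
        )
    if genomic.alignment_score - repeat.alignment_score > SCORE_MARGIN:
        return genomic
    return repeat


def dedup_pcr(records: Iterable[ReadRecord]) -> list[ReadRecord]:
    """Collapse PCR duplicates on (target, start, stop, UMI).

    The survivor is the lexicographically smallest read_id in each group
    (a stable, order-independent choice; counts are unaffected by which
    duplicate survives).
    """
    groups: dict[tuple, ReadRecord] = {}
    for r in records:
        if not r.umi:
            raise ValueError(f"record {r.read_id} lacks a UMI")
        key = (r.target, r.start, r.stop, r.umi)
        kept = groups.get(key)
        if kept is None or r.read_id < kept.read_id:
            groups[key] = r
    return sorted(groups.values(), key=lambda r: r.read_id)


def relative_information(
    p: np.ndarray, q: np.ndarray, pseudo: Optional[float] = None
) -> np.ndarray:
    """Element-wise p_i * log2(p_i / q_i) in bits.

    ``pseudo`` (half the reciprocal library depth) replaces a zero in
    exactly one of p_i/q_i; both-zero elements contribute 0 bits.
    """
    p = np.asarray(p, dtype=float).copy()
    q = np.asarray(q, dtype=float).copy()
    if ((p < 0) | (p > 1)).any() or ((q < 0) | (q > 1)).any():
        raise ValueError("fractions must lie in [0, 1]")
    if pseudo is not None:
        one_zero = (p == 0) ^ (q == 0)
        p[one_zero & (p == 0)] = pseudo
        q[one_zero & (q == 0)] = pseudo
    if ((q == 0) & (p > 0)).any():
        raise ValueError("q_i = 0 with p_i > 0: apply the pseudocount policy")
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = p[pos] * np.log2(p[pos] / q[pos])
    return out


@dataclass
class FamilyQuant:
    """Per-element read counts and relative information for IP vs input."""

    table: pd.DataFrame  # element, ip_count, input_count, p_i, q_i, information_bits
    ip_total: int
    input_total: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def quantify_families(
    ip_assignments: Sequence[FamilyAssignment],
    input_assignments: Sequence[FamilyAssignment],
    ip_total: int,
    input_total: int,
    extra_elements: Optional[dict[str, tuple[int, int]]] = None,
) -> FamilyQuant:
    """Per-family deduplicated counts and relative information.

    ``ip_total``/``input_total`` are the depth normalisers: all usable
    deduplicated pairs including unique genomic ones (discarded
    multi-family pairs are excluded).  ``extra_elements`` adds transcript-
    region groups (element -> (ip_count, input_count)).
    """
    ip_counts: dict[str, int] = {}
    in_counts: dict[str, int] = {}
    for a in ip_assignments:
        ip_counts[a.family_id] = ip_counts.get(a.family_id, 0) + 1
    for a in input_assignments:
        in_counts[a.family_id] = in_counts.get(a.family_id, 0) + 1
    if extra_elements:
        for name, (ipc, inc) in extra_elements.items():
            ip_counts[name] = ip_counts.get(name, 0) + ipc
            in_counts[name] = in_counts.get(name, 0) + inc
    elements = sorted(set(ip_counts) | set(in_counts))
    ipc = np.array([ip_counts.get(e, 0) for e in elements], dtype=float)
    inc = np.array([in_counts.get(e, 0) for e in elements], dtype=float)
    p = ipc / ip_total if ip_total else np.zeros_like(ipc)
    q = inc / input_total if input_total else np.zeros_like(inc)
    pseudo = 0.5 / max(ip_total, input_total, 1)
    info = relative_information(p, q, pseudo=pseudo)
    table = pd.DataFrame(
        {
            "element": elements,
            "ip_count": ipc.astype(int),
            "input_count": inc.astype(int),
            "p_i": p,
            "q_i": q,
            "information_bits": info,
        }
    )
    return FamilyQuant(table, ip_total, input_total)


def merged_replicate_information(
    quant1: FamilyQuant, quant2: FamilyQuant
) -> pd.DataFrame:
    """Merged relative information using the average IP fraction of the two
    replicates as p_i (input fractions averaged symmetrically)."""
    t1 = quant1.table.set_index("element")
    t2 = quant2.table.set_index("element")
    elements = sorted(set(t1.index) | set(t2.index))
    p = np.array([(t1["p_i"].get(e, 0.0) + t2["p_i"].get(e, 0.0)) / 2 for e in elements])
    q = np.array([(t1["q_i"].get(e, 0.0) + t2["q_i"].get(e, 0.0)) / 2 for e in elements])
    pseudo = 0.5 / max(quant1.ip_total, quant2.ip_total, quant1.input_total, 1)
    info = relative_information(p, q, pseudo=pseudo)
    return pd.DataFrame({"element": elements, "p_i": p, "q_i": q,
                         "information_bits": info})


def overlaps_masked_track(
    record: ReadRecord, masked: Sequence[tuple[int, int]]
) -> bool:
    """>= 1 nt overlap of a genomic record with a masked-element track."""
    return any(record.start < e and record.stop > s for s, e in masked)


def quantify_region(
    ip_count: int,
    input_count: int,
    ip_total: int,
    input_total: int,
    min_reads: int = 10,
) -> tuple[float, float, bool]:
    """(fold enrichment, p, eligible) for one transcript region.

    Eligible regions have >= 10 reads in one of IP/input and >= 10
    expected in the other given the depth ratio.  p comes from two-sided
    Fisher's exact, replaced by the Yates-corrected chi-square when all
    observed and expected cell values exceed 5.  Significance downstream
    is eligible & fold >= 4 & p <= 1e-5.
    """
    if not (0 <= ip_count <= ip_total and 0 <= input_count <= input_total):
        raise ValueError("totals must be >= counts >= 0")
    if ip_total == 0 or input_total == 0:
        return (np.nan, 1.0, False)
    exp_input = ip_count * input_total / ip_total
    exp_ip = input_count * ip_total / input_total
    eligible = (ip_count >= min_reads and exp_input >= min_reads) or (
        input_count >= min_reads and exp_ip >= min_reads
    )
    p_ip = ip_count / ip_total
    q_in = input_count / input_total
    if q_in == 0:
        fold = np.inf if p_ip > 0 else np.nan
    else:
        fold = p_ip / q_in
    table = np.array(
        [
            [ip_count, ip_total - ip_count],
            [input_count, input_total - input_count],
        ]
    )
    if table.sum() == 0:
        return (fold, 1.0, False)
    expected = stats.contingency.expected_freq(table) if table.min() >= 0 else None
    use_yates = (table > 5).all() and (expected > 5).all()
    if use_yates:
        p = float(stats.chi2_contingency(table, correction=True)[1])
    else:
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return (float(fold), p, bool(eligible))


def region_significant(
    fold: float, p: float, eligible: bool,
    min_fold: float = 4.0, max_p: float = 1e-5,
) -> bool:
    return bool(eligible and fold >= min_fold and p <= max_p)
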